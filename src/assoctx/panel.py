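"""Published summary statistics of the B. napus RIPR association platform.

The RIPR (Renewable Industrial Products from Rapeseed) diversity panel of
383 inbred/doubled-haploid accessions was functionally genotyped by leaf
mRNA-seq against the ordered Brassica A/C pan-transcriptome reference.
These constants are the platform's published bookkeeping quantities; the
functions derive the headline per-platform figures (marker density,
missing-call rate, mapped fraction, sequencing volume and significance
thresholds) from them.
"""

from __future__ import annotations

from .association import bonferroni_threshold

#: Accessions in the diversity panel.
N_ACCESSIONS = 383
#: SNP markers scored across the panel.
N_SNPS = 355_536
#: Markers with minor allele frequency > 0.01 (the SNP association tests).
N_SNPS_MAF_FILTERED = 256_397
#: CDS models with panel-mean expression > 0.4 RPKM (the GEM tests).
N_EXPRESSED_MODELS = 53_889
#: CDS gene models in the pan-transcriptome reference.
N_REFERENCE_MODELS = 116_098
#: Aggregate reference length in bases.
REFERENCE_LENGTH = 118_657_829
#: Reference bases covered by mapped reads (per-accession mean).
MAPPED_REFERENCE_BASES = 61_620_266
#: Mean sequence reads generated per accession.
MEAN_READS_PER_ACCESSION = 50_165_125
#: mRNA-seq read length in bases.
READ_LENGTH = 100
#: Allele calls made across the panel, and those missing.
ALLELE_CALLS_MADE = 127_153_561
MISSING_ALLELE_CALLS = 9_017_727


def snp_bonferroni_line(alpha: float = 0.05) -> float:
    """-log10 Bonferroni threshold over the MAF-filtered SNP markers."""
    return bonferroni_threshold(alpha, N_SNPS_MAF_FILTERED)


def gem_bonferroni_line(alpha: float = 0.05) -> float:
    """-log10 Bonferroni threshold over the expressed CDS models."""
    return bonferroni_threshold(alpha, N_EXPRESSED_MODELS)


def missing_call_percent() -> float:
    """Missing allele calls as a percentage of all possible calls.

    The denominator is accessions x scored SNPs (calls made plus missing).
    """
    return 100.0 * MISSING_ALLELE_CALLS / (N_ACCESSIONS * N_SNPS)


def snp_density_kb() -> float:
    """Mean reference kilobases per scored SNP (one SNP every ~0.33 kb)."""
    return REFERENCE_LENGTH / N_SNPS / 1_000


def mapped_transcriptome_percent() -> float:
    """Percentage of the reference transcriptome covered by mapped reads."""
    return 100.0 * MAPPED_REFERENCE_BASES / REFERENCE_LENGTH


def total_sequenced_bases() -> float:
    """Total mRNA-seq bases across the panel (reads x length x accessions)."""
    return float(N_ACCESSIONS) * MEAN_READS_PER_ACCESSION * READ_LENGTH
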