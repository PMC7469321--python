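"""Bundled reference data for the NPPA promoter methylation panel.

Ships the assayed CpG panel (GRCh37, reverse strand) and the published
per-group summary statistics for the two study samples (a community-based
discovery sample and an independent replication sample), so that the
desk-scale reproduction utilities and the demo pipeline run without any
external download.

Censored p-values reported only as "< 0.001" are represented by the
placeholder :data:`CENSORED_P`; every consumer in this package is invariant
to the exact placeholder as long as it stays strictly below 0.001.
"""

from __future__ import annotations

from .association import SummaryStats

#: Chromosome of the assayed promoter region.
NPPA_CHROM = "chr1"

#: Transcription start site coordinate (1-based, GRCh37) consistent with all
#: nine published (position, TSS-offset) pairs and both region endpoints.
NPPA_TSS = 11907840

#: Assayed region, 1-based inclusive (reverse strand).
NPPA_REGION = (11908117, 11908380)

NPPA_STRAND = "-"

#: (label, 1-based GRCh37 position) for the nine assayed CpG sites.
NPPA_SITE_POSITIONS = [
    ("CpG1", 11908353),
    ("CpG2", 11908348),
    ("CpG3", 11908299),
    ("CpG4", 11908200),
    ("CpG5", 11908182),
    ("CpG6", 11908178),
    ("CpG7", 11908168),
    ("CpG8", 11908165),
    ("CpG9", 11908142),
]

#: Published TSS-relative offsets (bp) for the nine sites.
NPPA_TSS_OFFSETS = {
    "CpG1": -513,
    "CpG2": -508,
    "CpG3": -459,
    "CpG4": -360,
    "CpG5": -342,
    "CpG6": -338,
    "CpG7": -328,
    "CpG8": -325,
    "CpG9": -302,
}

#: Group sizes (non-hypertensive, hypertensive).
DISCOVERY_N = (1389, 1109)
REPLICATION_N = (776, 995)

#: Per-site methylation % as (mean_nonHBP, sd_nonHBP, mean_HBP, sd_HBP).
#: "Average" is the per-sample mean over the nine sites.
DISCOVERY_METHYLATION = {
    "CpG1": (29.02, 5.13, 27.96, 5.28),
    "CpG2": (93.27, 2.46, 93.03, 2.59),
    "CpG3": (22.99, 3.84, 22.64, 3.83),
    "CpG4": (68.59, 6.36, 67.90, 6.62),
    "CpG5": (81.96, 4.81, 81.32, 4.98),
    "CpG6": (40.43, 6.05, 39.60, 6.18),
    "CpG7": (50.67, 6.34, 49.81, 6.54),
    "CpG8": (31.13, 6.33, 30.11, 6.48),
    "CpG9": (36.84, 7.63, 36.15, 7.87),
    "Average": (50.55, 4.69, 49.84, 4.88),
}

REPLICATION_METHYLATION = {
    "CpG1": (28.95, 5.24, 27.17, 5.05),
    "CpG2": (93.02, 2.40, 92.92, 2.72),
    "CpG3": (22.91, 4.20, 22.45, 3.76),
    "CpG4": (68.23, 6.74, 67.67, 6.85),
    "CpG5": (81.53, 4.93, 81.14, 5.28),
    "CpG6": (40.35, 6.18, 39.12, 6.20),
    "CpG7": (50.14, 6.39, 49.71, 6.77),
    "CpG8": (30.48, 6.41, 29.82, 6.56),
    "CpG9": (36.21, 7.75, 36.63, 7.91),
    "Average": (50.20, 4.78, 49.62, 5.06),
}

#: Placeholder for p-values censored in the source tables as "< 0.001".
CENSORED_P = 0.0005

#: Published group-comparison p-values for the discovery sample, per site.
#: Values below 0.001 were censored at source; see :data:`CENSORED_P`.
DISCOVERY_GROUP_P = {
    "CpG1": CENSORED_P,
    "CpG2": 0.019,
    "CpG3": 0.024,
    "CpG4": 0.008,
    "CpG5": 0.001,
    "CpG6": CENSORED_P,
    "CpG7": CENSORED_P,
    "CpG8": CENSORED_P,
    "CpG9": 0.027,
}

#: Current-smoking counts by hypertension status in the discovery sample,
#: as a 2x2 table (smoker/non-smoker x non-HBP/HBP).
DISCOVERY_SMOKING_2X2 = {
    "smoker_nonhbp": 281,
    "nonsmoker_nonhbp": DISCOVERY_N[0] - 281,
    "smoker_hbp": 301,
    "nonsmoker_hbp": DISCOVERY_N[1] - 301,
}

#: Published adjusted SBP effect for CpG1 (beta per 5% methylation, SE)
#: in each sample; inputs to the meta-analysis examples.
CPG1_SBP_EFFECTS = [
    ("discovery", -0.96, 0.29),
    ("replication", -2.22, 0.60),
]


def group_summary(sample: str, site: str) -> SummaryStats:
    """Published group moments for one site as a :class:`SummaryStats`.

    Parameters
    ----------
    sample:
        ``"discovery"`` or ``"replication"``.
    site:
        Site label (``CpG1`` .. ``CpG9``) or ``"Average"``.
    """
    if sample == "discovery":
        n1, n2 = DISCOVERY_N
        table = DISCOVERY_METHYLATION
    elif sample == "replication":
        n1, n2 = REPLICATION_N
        table = REPLICATION_METHYLATION
    else:
        raise ValueError(f"unknown sample {sample!r}")
    m1, s1, m2, s2 = table[site]
    return SummaryStats(n1=n1, n2=n2, mean1=m1, mean2=m2, sd1=s1, sd2=s2)
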