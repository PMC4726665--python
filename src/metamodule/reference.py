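"""Published summary statistics of the six BMD expression studies.

These printed per-study characteristics and candidate-gene meta-analysis
results are inputs that the synthetic-data generator emulates and that the
analytic self-checks consume. The raw studies themselves (GEO/ArrayExpress
accessions) are not required by this package.
"""

from __future__ import annotations

# Per-study characteristics: accession, sample sizes (high/low BMD), outliers
# removed during the original preprocessing, platform and tissue.
STUDIES = [
    {"accession": "GSE56815", "n_high": 40, "n_low": 40, "outliers_high": 2,
     "outliers_low": 1, "platform": "HG-U133A", "tissue": "peripheral blood monocytes"},
    {"accession": "GSE7158", "n_high": 14, "n_low": 12, "outliers_high": 2,
     "outliers_low": 0, "platform": "HG-U133_Plus_2", "tissue": "peripheral blood monocytes"},
    {"accession": "GSE2208", "n_high": 10, "n_low": 9, "outliers_high": 0,
     "outliers_low": 0, "platform": "HG-U133A", "tissue": "peripheral blood monocytes"},
    {"accession": "E-MEXP-1618", "n_high": 45, "n_low": 39, "outliers_high": 1,
     "outliers_low": 3, "platform": "HG-U133_Plus_2", "tissue": "bone biopsies"},
    {"accession": "GSE7429", "n_high": 10, "n_low": 10, "outliers_high": 2,
     "outliers_low": 1, "platform": "HG-U133A", "tissue": "circulating B cells"},
    {"accession": "GSE13850", "n_high": 10, "n_low": 10, "outliers_high": 0,
     "outliers_low": 1, "platform": "HG-U133A", "tissue": "circulating B cells"},
]

# Candidate genes with their published meta-analysis summaries: pooled SMD and
# its SD, z statistic, effect-size meta p, Fisher's combined statistic (k = 6
# studies, 12 df) and its p, plus gene-level GWAS replication p-values.
CANDIDATE_GENES = {
    "ESR1": {"smd": 0.49, "smd_sd": 0.24, "z": 2.05, "es_p": 2.67e-2,
             "fisher_stat": 31.81, "fisher_p": 1.48e-3,
             "gefos2_p": 1.13e-11, "meta7_p": 2.52e-7},
    "MAP3K3": {"smd": -0.53, "smd_sd": 0.28, "z": -1.90, "es_p": 3.95e-2,
               "fisher_stat": 46.93, "fisher_p": 4.79e-6,
               "gefos2_p": 2.25e-2, "meta7_p": 2.65e-2},
    "PYGM": {"smd": -0.70, "smd_sd": 0.13, "z": -5.17, "es_p": 2.25e-7,
             "fisher_stat": 42.85, "fisher_p": 2.40e-5,
             "gefos2_p": 2.67e-3, "meta7_p": 6.67e-4},
    "RAC1": {"smd": -0.45, "smd_sd": 0.25, "z": -1.76, "es_p": 5.50e-2,
             "fisher_stat": 40.90, "fisher_p": 5.10e-5,
             "gefos2_p": 2.74e-2, "meta7_p": 4.41e-2},
    "SYK": {"smd": 0.52, "smd_sd": 0.26, "z": 1.99, "es_p": 3.13e-2,
            "fisher_stat": 49.72, "fisher_p": 1.57e-6,
            "gefos2_p": 2.51e-3, "meta7_p": 3.84e-2},
}

N_STUDIES = len(STUDIES)


def total_samples() -> tuple[int, int, int]:
    """(total, high-BMD, low-BMD) subject counts summed over the studies."""
    high = sum(s["n_high"] for s in STUDIES)
    low = sum(s["n_low"] for s in STUDIES)
    return high + low, high, low
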