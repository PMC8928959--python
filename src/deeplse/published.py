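"""Published benchmark statistics for antioxidant-protein predictors.

These are printed results from the literature, consumed as fixed inputs:
per-method test-set class recalls on the standard 53/312 antioxidant
benchmark test split, and per-protein identification outcomes of three
predictors on an independent set of 22 reviewed antioxidant proteins
(UniProtKB accessions).  They are used to exercise the metric-identity
and independent-set bookkeeping routines, not produced by this package.
"""

from __future__ import annotations

# Test-split class recalls (sensitivity, specificity) and the balanced
# statistics derived from them as printed, for three predictors.
BENCHMARK_TEST_RATES: dict[str, dict[str, float]] = {
    "naive_bayes": {
        "sensitivity": 0.720,
        "specificity": 0.660,
        "printed_bacc": 0.690,
        "printed_yi": 0.38,
    },
    "aodpred_svm": {
        "sensitivity": 0.750,
        "specificity": 0.744,
        "printed_bacc": 0.747,
        "printed_yi": 0.49,
    },
    "aop_lse": {
        "sensitivity": 0.674,
        "specificity": 0.849,
        "printed_bacc": 0.762,
        "printed_yi": 0.52,
    },
}

# Benchmark test-split sizes behind the rates above.
BENCHMARK_TEST_SIZE = {"n_pos": 53, "n_neg": 312}

_INDEPENDENT_PROTEINS = (
    # (accession, AODPred correct, Vote9 correct, AoP-LSE correct)
    ("P9WQB7", True, False, True),
    ("P9WHH9", False, False, True),
    ("P9WIS7", False, True, True),
    ("P9WG35", True, False, True),
    ("P9WGE9", True, False, True),
    ("P9WQB5", True, False, True),
    ("P9WIE3", True, False, True),
    ("P0CU34", True, False, True),
    ("Q5ACV9", False, False, True),
    ("P9WHH8", False, True, True),
    ("P9WIE1", False, True, True),
    ("P9WIS6", False, False, True),
    ("P9WQB6", True, False, True),
    ("P9WID9", True, False, True),
    ("O17433", True, False, False),
    ("P9WIE0", False, False, True),
    ("P9WID8", True, False, True),
    ("P9WGE8", True, False, True),
    ("C0HK70", True, False, True),
    ("P9WQB4", True, False, True),
    ("P9WG34", True, False, True),
    ("P9WIE2", True, False, True),
)

# Per-protein outcome maps, one per predictor, for the tally harness.
INDEPENDENT_SET_OUTCOMES: dict[str, dict[str, bool]] = {
    "aodpred": {acc: a for acc, a, _, _ in _INDEPENDENT_PROTEINS},
    "vote9": {acc: v for acc, _, v, _ in _INDEPENDENT_PROTEINS},
    "aop_lse": {acc: p for acc, _, _, p in _INDEPENDENT_PROTEINS},
}
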