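"""Bundled example tables from a molluscan CNS-injury regeneration study.

These are published-style summary statistics (means, SEMs, group sizes and
regulated-gene counts) of the kind this package's estimators consume; they
drive the worked examples and the reproduction script. Raw per-subject
measurements are not public, so only summary-level inputs are bundled.
"""

from __future__ import annotations

from .outcomes import GroupSummary

__all__ = [
    "de_counts",
    "distal_neurite_summaries",
    "timecourse_fold_changes",
    "locomotion_day10_summaries",
]


def de_counts() -> dict[str, int]:
    """Regulated-gene counts from the 4 sham vs 4 crush array comparison:
    10,333 unique probes tested, 348 significant at raw p < 0.05, of which
    42 up- and 25 down-regulated at >= 2-fold."""
    return {"n_tested": 10333, "n_significant": 348, "n_up": 42, "n_down": 25}


def distal_neurite_summaries() -> dict[int, list[GroupSummary]]:
    """Distal-neurite net length change (um) after axotomy, mean +/- SEM,
    n = 14 cells per treatment, at 10/24/36 h post treatment."""
    data = {
        10: [("CM", 14.2, 2.4), ("control_siRNA", 17.6, 2.7), ("cebp_siRNA_1", -0.3, 3.0), ("cebp_siRNA_2", 1.2, 0.7)],
        24: [("CM", 21.9, 3.1), ("control_siRNA", 21.2, 3.7), ("cebp_siRNA_1", -1.8, 2.9), ("cebp_siRNA_2", 0.1, 1.3)],
        36: [("CM", 29.1, 3.9), ("control_siRNA", 24.4, 4.0), ("cebp_siRNA_1", -5.9, 2.8), ("cebp_siRNA_2", -3.0, 2.2)],
    }
    return {
        t: [GroupSummary(g, m, s, 14, units="um") for g, m, s in rows]
        for t, rows in data.items()
    }


def timecourse_fold_changes() -> dict[float, float]:
    """Published crush/sham relative-expression point estimates for the focal
    transcription factor (vs the GAPDH control) at 1, 3 and 5 h post injury.
    Used as ground-truth ratios when simulating recovery experiments."""
    return {1.0: 7.36, 3.0: 2.35, 5.0: 1.98}


def locomotion_day10_summaries() -> list[GroupSummary]:
    """Crawled distance (cm per 10 min) on day 10 post operation."""
    rows = [
        ("sham_saline", 10.28, 1.28, 6),
        ("sham_control_siRNA", 12.23, 1.36, 6),
        ("sham_cebp_siRNA", 11.56, 2.75, 5),
        ("crush_saline", 10.65, 2.84, 4),
        ("crush_control_siRNA", 10.17, 1.0, 5),
        ("crush_cebp_siRNA", 4.99, 0.71, 3),
    ]
    return [GroupSummary(g, m, s, n, units="cm/10min") for g, m, s, n in rows]
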