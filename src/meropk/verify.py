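"""Verification harness: recompute statistics from the shipped printed counts.

The study's patient-level data are unavailable, but its printed band counts
are sufficient input to recompute every percentage, the mortality odds
ratio with its Woolf CI, the chi-square p-value and the phase-attainment
comparison.  This module loads the packaged counts, reruns the stats and
exposure modules on them, and diffs against the printed reference values.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .exposure import BandTally, ExposureBand
from .stats import chi_square, odds_ratio_woolf, two_proportion_test, ContingencyTable2x2

__all__ = ["load_published_counts", "tally_from_counts", "verify_published_tables"]


def load_published_counts(path: str | Path | None = None) -> dict:
    """Load the packaged printed-count fixture (or a user-supplied JSON)."""
    if path is not None:
        return json.loads(Path(path).read_text())
    ref = resources.files("meropk.data").joinpath("published_counts.json")
    return json.loads(ref.read_text())


def tally_from_counts(counts: list[int]) -> BandTally:
    """Rebuild a BandTally from five printed band counts (<2 ... >24)."""
    return BandTally.from_counts(dict(zip(ExposureBand, counts)))


def verify_published_tables(counts: dict | None = None, alpha: float = 0.05) -> dict:
    """Recompute all printed-table quantities and diff against the printed values.

    Returns a report dict with the recomputed numbers, the printed
    references and per-quantity differences.
    """
    data = counts if counts is not None else load_published_counts()
    therapeutic = ExposureBand.therapeutic_8_16
    harmful = ExposureBand.harmful_above_24

    t_first = tally_from_counts(data["concentration_tallies"]["software_guided_first48"]["counts"])
    t_post = tally_from_counts(data["concentration_tallies"]["tdm_guided_post48"]["counts"])
    strat = {k: tally_from_counts(v["counts"]) for k, v in data["strategy_tallies"].items()}

    m = data["mortality_2x2"]
    table = ContingencyTable2x2(a=m["a"], b=m["b"], c=m["c"], d=m["d"])
    or_res = odds_ratio_woolf(table, alpha=alpha)
    chi = chi_square(table.to_array(), yates_correction=False, fisher_when_sparse=False)

    k1, n1 = data["attainment_comparison"]["first48_therapeutic"]
    k2, n2 = data["attainment_comparison"]["post48_therapeutic"]
    attain = two_proportion_test(k1, n1, k2, n2)

    recomputed = {
        "therapeutic_pct_first48": t_first.percent(therapeutic),
        "therapeutic_pct_post48": t_post.percent(therapeutic),
        "harmful_pct_first48": t_first.percent(harmful),
        "individualized_ci_therapeutic_pct": strat["individualized_ci"].percent(therapeutic),
        "standard_bolus_therapeutic_pct": strat["standard_bolus"].percent(therapeutic),
        "mortality_or": round(or_res.or_value, 3),
        "mortality_or_ci": [round(or_res.ci_lower, 3), round(or_res.ci_upper, 3)],
        "mortality_p": round(chi.p_value, 3),
    }
    printed = data["printed_reference"]
    diffs = {}
    for key, ref in printed.items():
        got = recomputed[key]
        if isinstance(ref, list):
            diffs[key] = [round(g - r, 6) for g, r in zip(got, ref)]
        else:
            diffs[key] = round(got - ref, 6)
    return {
        "recomputed": recomputed,
        "printed": printed,
        "diff": diffs,
        "attainment_two_proportion_p": round(attain.p_value, 4),
        "tallies": {
            "first48": t_first.to_frame().to_dict(orient="records"),
            "post48": t_post.to_frame().to_dict(orient="records"),
            **{k: v.to_frame().to_dict(orient="records") for k, v in strat.items()},
        },
    }
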