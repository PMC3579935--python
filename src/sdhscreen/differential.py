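"""Differential drug-effect scoring between mutant and reference strains.

For a compound tested on a mutant and a reference strain, each with and
without drug, three unitless differentials compare how strongly the drug
shifted each growth parameter in each strain:

    delta_S = S_ref,drug / S_ref,ctrl  -  S_mut,drug / S_mut,ctrl
    delta_R = R_ref,drug / R_ref,ctrl  -  R_mut,drug / R_mut,ctrl
    delta_L = L_mut,drug / L_mut,ctrl  -  L_ref,drug / L_ref,ctrl

where S is the maximum saturation reached by the culture (sum of fitted
phase saturations above baseline), and R and L are the maximal rate and
lag of the glycolytic (first) phase.  The sign convention makes positive
values always mean "the mutant is more inhibited": drug-shrunken mutant
saturation or rate lowers the mutant ratio (raising delta_S/delta_R),
whereas a drug-lengthened mutant lag raises the mutant ratio, so the lag
differential is oriented mutant-minus-reference.

A compound is called mutant-selective / reference-selective when any
differential strictly exceeds the corresponding threshold, and
nonselective otherwise; exact ties break toward nonselective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthCurveModel, GrowthFitResult

__all__ = [
    "GrowthSummary",
    "DifferentialScore",
    "Thresholds",
    "delta_scores",
    "classify",
    "score_table",
    "marker_concordance",
]

CALLS = ("mutant_selective", "reference_selective", "nonselective", "indeterminate")


@dataclass(frozen=True)
class GrowthSummary:
    """(S, R, L) triple extracted from one growth-curve fit."""

    saturation: float  # total growth above baseline, OD
    max_rate: float    # glycolytic-phase maximal slope, OD/h
    lag_h: float       # glycolytic-phase lag, h
    converged: bool = True

    @classmethod
    def from_fit(cls, fit: GrowthFitResult | GrowthCurveModel) -> "GrowthSummary":
        if isinstance(fit, GrowthCurveModel):
            fit = fit.result_()
        if fit.no_growth or not fit.phases:
            return cls(saturation=0.0, max_rate=0.0, lag_h=0.0, converged=fit.converged)
        first = min(fit.phases, key=lambda p: p.inflection_h)
        return cls(
            saturation=float(sum(p.saturation for p in fit.phases)),
            max_rate=float(first.max_rate),
            lag_h=float(first.lag_h),
            converged=fit.converged,
        )


@dataclass
class DifferentialScore:
    compound_id: str
    conc_um: float
    delta_s: float
    delta_r: float
    delta_l: float
    call: str = "indeterminate"


@dataclass(frozen=True)
class Thresholds:
    """Minimum differential (strict) for a selective call; explicit by design."""

    delta_s: float
    delta_r: float
    delta_l: float


def _ratio(drug: float, ctrl: float, floor: float) -> float:
    denom = max(ctrl, floor)
    if denom <= 0:
        raise ValueError("control parameter and floor are both non-positive")
    return drug / denom


def delta_scores(
    ref_ctrl: GrowthSummary,
    ref_drug: GrowthSummary,
    mut_ctrl: GrowthSummary,
    mut_drug: GrowthSummary,
    compound_id: str = "",
    conc_um: float = np.nan,
    lag_floor_h: float = 0.25,
    param_floor: float = 1e-6,
) -> DifferentialScore:
    """Compute (delta_S, delta_R, delta_L) for one matched strain quadruple.

    All four fits must have converged; a control lag of zero is replaced by
    ``lag_floor_h`` so the lag ratio stays defined.  Raises on
    non-converged input rather than emitting silent NaNs.
    """
    quad = (ref_ctrl, ref_drug, mut_ctrl, mut_drug)
    if not all(q.converged for q in quad):
        raise ValueError("all four fits must converge before scoring")
    ds = _ratio(ref_drug.saturation, ref_ctrl.saturation, param_floor) - \
        _ratio(mut_drug.saturation, mut_ctrl.saturation, param_floor)
    dr = _ratio(ref_drug.max_rate, ref_ctrl.max_rate, param_floor) - \
        _ratio(mut_drug.max_rate, mut_ctrl.max_rate, param_floor)
    dl = _ratio(mut_drug.lag_h, mut_ctrl.lag_h, lag_floor_h) - \
        _ratio(ref_drug.lag_h, ref_ctrl.lag_h, lag_floor_h)
    return DifferentialScore(
        compound_id=compound_id, conc_um=conc_um,
        delta_s=float(ds), delta_r=float(dr), delta_l=float(dl),
    )


def classify(score: DifferentialScore, thresholds: Thresholds) -> str:
    """Selective/nonselective call for one score (strict inequalities).

    A compound pushed past the threshold in both directions on different
    metrics is contradictory and returns ``indeterminate``.
    """
    deltas = (score.delta_s, score.delta_r, score.delta_l)
    thr = (thresholds.delta_s, thresholds.delta_r, thresholds.delta_l)
    if any(not np.isfinite(d) for d in deltas):
        return "indeterminate"
    mutant = any(d > t for d, t in zip(deltas, thr))
    reference = any(d < -t for d, t in zip(deltas, thr))
    if mutant and reference:
        return "indeterminate"
    if mutant:
        return "mutant_selective"
    if reference:
        return "reference_selective"
    return "nonselective"


def score_table(
    fits: pd.DataFrame,
    mutant: str,
    reference: str,
    thresholds: Thresholds,
    lag_floor_h: float = 0.25,
) -> pd.DataFrame:
    """Score every (compound, concentration) with a complete strain quadruple.

    ``fits`` holds one row per fitted curve with columns: strain,
    compound_id, conc_um, drug_present (bool), saturation, max_rate, lag_h,
    converged.  A compound tested at several concentrations receives one
    row per concentration plus an ``any_selective`` flag — a compound is
    reported differential when it is selective at one or more tested
    concentrations.
    """
    required = {"strain", "compound_id", "conc_um", "drug_present",
                "saturation", "max_rate", "lag_h", "converged"}
    if missing := required - set(fits.columns):
        raise ValueError(f"fits table missing columns: {sorted(missing)}")

    def _summary(rows: pd.DataFrame) -> GrowthSummary | None:
        if rows.empty:
            return None
        r = rows.iloc[0]
        return GrowthSummary(r["saturation"], r["max_rate"], r["lag_h"], bool(r["converged"]))

    records = []
    drugged = fits[fits["drug_present"]]
    for (cid, conc), _grp in drugged.groupby(["compound_id", "conc_um"], sort=True):
        parts = {}
        for strain, with_drug in ((reference, False), (reference, True),
                                  (mutant, False), (mutant, True)):
            sel = fits[(fits["strain"] == strain) & (fits["drug_present"] == with_drug)]
            if with_drug:
                sel = sel[(sel["compound_id"] == cid) & (sel["conc_um"] == conc)]
            parts[(strain, with_drug)] = _summary(sel)
        if any(v is None for v in parts.values()):
            raise ValueError(f"incomplete strain quadruple for {cid} at {conc} µM")
        quad = (parts[(reference, False)], parts[(reference, True)],
                parts[(mutant, False)], parts[(mutant, True)])
        if not all(q.converged for q in quad):
            records.append({"compound_id": cid, "conc_um": conc,
                            "delta_s": np.nan, "delta_r": np.nan, "delta_l": np.nan,
                            "call": "indeterminate"})
            continue
        sc = delta_scores(*quad, compound_id=cid, conc_um=conc, lag_floor_h=lag_floor_h)
        sc.call = classify(sc, thresholds)
        records.append({"compound_id": cid, "conc_um": conc,
                        "delta_s": sc.delta_s, "delta_r": sc.delta_r,
                        "delta_l": sc.delta_l, "call": sc.call})
    out = pd.DataFrame(records)
    if out.empty:
        return out
    sel = out["call"].isin(["mutant_selective", "reference_selective"])
    out["any_selective"] = out["compound_id"].isin(set(out.loc[sel, "compound_id"]))
    return out.sort_values(["compound_id", "conc_um"]).reset_index(drop=True)


def marker_concordance(
    fits_ref: pd.DataFrame,
    fits_marker: pd.DataFrame,
    tolerance: float = 0.2,
) -> tuple[bool, pd.DataFrame]:
    """Check that drug effects on two reference-like strains are indistinguishable.

    For each matched (compound, concentration), the drug/control ratio of
    each growth parameter is compared between the reference strain and the
    marker-bearing control strain; a relative difference above
    ``tolerance`` on any parameter flags the compound as discordant
    (possible marker/acetyltransferase artifact).

    Both tables use the fits schema of :func:`score_table` restricted to a
    single strain each.  Raises on an empty comparison set: no matched
    conditions is an error, not a vacuous pass.
    """
    def _ratios(df: pd.DataFrame) -> pd.DataFrame:
        ctrl = df[~df["drug_present"]]
        if ctrl.empty:
            raise ValueError("missing no-drug control fits")
        c = ctrl.iloc[0]
        drugged = df[df["drug_present"]].copy()
        drugged["ratio_s"] = drugged["saturation"] / max(c["saturation"], 1e-6)
        drugged["ratio_r"] = drugged["max_rate"] / max(c["max_rate"], 1e-6)
        drugged["ratio_l"] = drugged["lag_h"] / max(c["lag_h"], 0.25)
        return drugged[["compound_id", "conc_um", "ratio_s", "ratio_r", "ratio_l"]]

    merged = _ratios(fits_ref).merge(
        _ratios(fits_marker), on=["compound_id", "conc_um"],
        suffixes=("_ref", "_marker"), how="inner",
    )
    if merged.empty:
        raise ValueError("no matched (compound, concentration) conditions to compare")
    rows = []
    for _, r in merged.iterrows():
        rel = {}
        for p in ("s", "r", "l"):
            a, b = r[f"ratio_{p}_ref"], r[f"ratio_{p}_marker"]
            rel[p] = abs(a - b) / max(abs(a), abs(b), 1e-12)
        rows.append({
            "compound_id": r["compound_id"], "conc_um": r["conc_um"],
            "rel_diff_s": rel["s"], "rel_diff_r": rel["r"], "rel_diff_l": rel["l"],
            "concordant": all(v <= tolerance for v in rel.values()),
        })
    report = pd.DataFrame(rows)
    return bool(report["concordant"].all()), report
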