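"""Stage-I screening analytics: dispensing arithmetic, percent inhibition,
z-factor quality control, and hit calling.

Endpoint absorbances from 384-well screening plates are normalized per
plate and per read time into percent inhibition,

    PI = 100 * (1 - (test - blank) / (control - blank)),

which places no-compound (negative-control) wells at 0% and media blanks
at 100%.  Assay quality is summarized by the z-factor

    z = 1 - 3 * (sigma_p + sigma_n) / |mu_p - mu_n|

computed on the percent-inhibition values of positive and negative
controls (sample standard deviations, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCError",
    "percent_inhibition",
    "z_factor",
    "ControlStats",
    "summarize_plate",
    "plate_qc",
    "call_hits",
    "DispenseProtocol",
    "DispenseResult",
    "dispense_concentration",
]


class QCError(ValueError):
    """Raised when a plate fails a quality-control precondition."""


def percent_inhibition(test, control_mean, blank_mean):
    """Percent inhibition of a test well relative to plate controls.

    Values above 100 (test below blank) and below 0 (growth stimulation)
    are passed through unclipped.  ``control_mean`` must exceed
    ``blank_mean``; anything else indicates a failed (no-growth) plate.
    """
    test = np.asarray(test, dtype=float)
    if np.any(np.asarray(control_mean) <= np.asarray(blank_mean)):
        raise QCError("control mean must exceed blank mean (no-growth control failure)")
    pi = 100.0 * (1.0 - (test - blank_mean) / (control_mean - blank_mean))
    return pi if pi.ndim else float(pi)


@dataclass(frozen=True)
class ControlStats:
    """Mean/sd of percent inhibition for positive and negative controls."""

    mu_p: float
    sigma_p: float
    n_p: int
    mu_n: float
    sigma_n: float
    n_n: int

    @property
    def z_factor(self) -> float:
        return z_factor_from_stats(self.mu_p, self.sigma_p, self.mu_n, self.sigma_n)


def z_factor_from_stats(mu_p: float, sigma_p: float, mu_n: float, sigma_n: float) -> float:
    sep = abs(mu_p - mu_n)
    if sep == 0:
        raise QCError("z-factor undefined: control means are equal")
    return 1.0 - 3.0 * (sigma_p + sigma_n) / sep


def z_factor(pos, neg, ddof: int = 1) -> float:
    """Assay z-factor from positive- and negative-control percent inhibition.

    Always <= 1; 1 only for noiseless, separated controls.  Negative values
    indicate overlapping controls unsuitable for screening.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise QCError("need >= 2 values per control group")
    return z_factor_from_stats(
        float(pos.mean()), float(pos.std(ddof=ddof)),
        float(neg.mean()), float(neg.std(ddof=ddof)),
    )


def _check_reads_map(reads: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    required_r = {"plate_id", "well", "time_min", "value"}
    required_m = {"plate_id", "well", "role"}
    if missing := required_r - set(reads.columns):
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    if missing := required_m - set(plate_map.columns):
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    if reads.duplicated(["plate_id", "well", "time_min"]).any():
        raise ValueError("duplicate (plate, well, read time) in reads")
    merged = reads.merge(plate_map, on=["plate_id", "well"], how="left", validate="m:1")
    if merged["role"].isna().any():
        bad = merged.loc[merged["role"].isna(), ["plate_id", "well"]].drop_duplicates()
        raise ValueError(f"plate map does not cover wells: {bad.to_records(index=False)[:5]}")
    return merged


def summarize_plate(reads: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Attach percent inhibition to every well, per plate and read time.

    Control and blank means are computed from the same plate and read time
    only.  Returns the merged long table with ``read_time_h``,
    ``control_mean``, ``blank_mean`` and ``percent_inhibition`` columns for
    every well (compound wells and controls alike, so control PI
    distributions can feed z-factor QC).
    """
    merged = _check_reads_map(reads, plate_map)
    merged = merged.copy()
    merged["read_time_h"] = merged["time_min"] / 60.0

    out = []
    for (plate, t), grp in merged.groupby(["plate_id", "read_time_h"], sort=True):
        neg = grp.loc[grp["role"] == "neg_control", "value"]
        blank = grp.loc[grp["role"] == "blank", "value"]
        if neg.empty or blank.empty:
            raise QCError(f"plate {plate} at {t} h lacks negative controls or blanks")
        cm, bm = float(neg.mean()), float(blank.mean())
        grp = grp.copy()
        grp["control_mean"] = cm
        grp["blank_mean"] = bm
        grp["percent_inhibition"] = percent_inhibition(grp["value"].to_numpy(), cm, bm)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def plate_qc(pi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-plate, per-read-time control statistics and z-factors.

    Expects the output of :func:`summarize_plate` on a plate that contains
    positive controls.
    """
    rows = []
    for (plate, t), grp in pi_table.groupby(["plate_id", "read_time_h"], sort=True):
        pos = grp.loc[grp["role"] == "pos_control", "percent_inhibition"].to_numpy()
        neg = grp.loc[grp["role"] == "neg_control", "percent_inhibition"].to_numpy()
        if len(pos) < 2 or len(neg) < 2:
            raise QCError(f"plate {plate} at {t} h lacks control replicates for z-factor")
        stats = ControlStats(
            mu_p=float(pos.mean()), sigma_p=float(pos.std(ddof=1)), n_p=len(pos),
            mu_n=float(neg.mean()), sigma_n=float(neg.std(ddof=1)), n_n=len(neg),
        )
        rows.append({
            "plate_id": plate, "read_time_h": t,
            "mu_p": stats.mu_p, "sigma_p": stats.sigma_p, "n_p": stats.n_p,
            "mu_n": stats.mu_n, "sigma_n": stats.sigma_n, "n_n": stats.n_n,
            "z_factor": stats.z_factor,
            "suitable_for_hts": stats.z_factor > 0.5,
        })
    return pd.DataFrame(rows)


def call_hits(pi_table: pd.DataFrame, threshold: float, read_time_h: float) -> pd.DataFrame:
    """Compounds whose percent inhibition meets ``threshold`` at one read time.

    The threshold is a required, explicit parameter (there is no default in
    the pipeline run record).  Ordering is deterministic: PI descending,
    then compound id.
    """
    if "read_time_h" not in pi_table.columns:
        raise ValueError("pi_table must come from summarize_plate")
    at_t = pi_table[np.isclose(pi_table["read_time_h"], read_time_h)]
    if at_t.empty:
        raise ValueError(f"no reads at {read_time_h} h in table")
    comp = at_t[(at_t["role"] == "compound") & (at_t["compound_id"] != "")]
    hits = comp[comp["percent_inhibition"] >= threshold]
    hits = hits.sort_values(
        ["percent_inhibition", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return hits[["compound_id", "plate_id", "well", "read_time_h", "percent_inhibition"]]


# ----------------------------------------------------------------------
# dispensing / dilution arithmetic
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DispenseProtocol:
    """Acoustic-dispensing protocol for one compound well.

    Defaults mirror the screening protocol: 20 droplets of 2.5 nL of 10 mM
    DMSO stock into 10 µL pre-dispensed medium (5x intermediate), topped up
    with 30 µL medium, then 10 µL of culture inoculum.
    """

    stock_conc_mm: float = 10.0
    droplet_vol_nl: float = 2.5
    n_droplets: int = 20
    predispensed_vol_ul: float = 10.0
    topup_vol_ul: float = 30.0
    inoculum_vol_ul: float = 10.0
    solvent: str = "DMSO"

    def __post_init__(self) -> None:
        if min(self.stock_conc_mm, self.droplet_vol_nl, self.predispensed_vol_ul,
               self.topup_vol_ul, self.inoculum_vol_ul) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")

    @property
    def dispensed_vol_ul(self) -> float:
        return self.n_droplets * self.droplet_vol_nl / 1000.0

    @property
    def compound_nmol(self) -> float:
        # mM == nmol/µL, so amount = stock * dispensed volume
        return self.stock_conc_mm * self.dispensed_vol_ul


@dataclass(frozen=True)
class DispenseResult:
    """Concentration and solvent fraction at one protocol stage.

    ``conc_um``/``solvent_pct`` use full volume accounting (droplet volume
    included in the denominator); the ``nominal_*`` fields ignore the
    dispensed droplet volume, matching conventional protocol arithmetic.
    """

    stage: str
    conc_um: float
    solvent_pct: float
    nominal_conc_um: float
    nominal_solvent_pct: float
    total_vol_ul: float


_STAGES = ("after_dispense", "after_topup", "final_assay")


def dispense_concentration(p: DispenseProtocol, stage: str) -> DispenseResult:
    """Mass-balance compound concentration and solvent fraction at a stage.

    Compound amount is conserved across stages; only the cumulative volume
    changes (after_dispense -> after_topup -> final_assay).
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    nominal_vol = p.predispensed_vol_ul
    if stage in ("after_topup", "final_assay"):
        nominal_vol += p.topup_vol_ul
    if stage == "final_assay":
        nominal_vol += p.inoculum_vol_ul
    full_vol = nominal_vol + p.dispensed_vol_ul

    amount = p.compound_nmol  # nmol
    # µM == nmol/mL
    conc = amount / (full_vol / 1000.0)
    nominal = amount / (nominal_vol / 1000.0)
    solvent = 100.0 * p.dispensed_vol_ul / full_vol
    nominal_solvent = 100.0 * p.dispensed_vol_ul / nominal_vol
    return DispenseResult(
        stage=stage,
        conc_um=conc,
        solvent_pct=solvent,
        nominal_conc_um=nominal,
        nominal_solvent_pct=nominal_solvent,
        total_vol_ul=full_vol,
    )
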