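"""End-to-end three-stage screen orchestration.

Stage I  — endpoint screen of the mutant strain in 384-well plates:
           percent inhibition, z-factor QC on a control plate, hit calling.
Stage II — high-resolution growth curves for each hit on mutant and
           reference strains with and without drug; growth-model fits;
           differential (delta) scoring and selectivity calls.
Stage III— marker-strain concordance: compounds selective in Stage II are
           re-tested against a marker-bearing but otherwise wild-type-like
           strain to exclude selection-marker artifacts.

Every random draw derives from the single seed recorded in the run
manifest, so re-running a manifest reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import Thresholds, marker_concordance, score_table
from .growth import fit_growth
from .plates import call_hits, plate_qc, summarize_plate
from .simulate import (
    DrugEffect,
    DrugEffectModel,
    SimConfig,
    curves_to_frame,
    gen_control_plate,
    gen_growth_curve,
    gen_screen_plate,
    nhp6a_null,
    sdh2_null,
    wild_type,
)

__all__ = ["default_config", "run_screen", "report", "COMPOUND_CLASSES"]

_ARCHETYPES = {"wt": wild_type, "sdh2": sdh2_null, "nhp6a": nhp6a_null}

# Effect archetypes for the synthetic Stage-II truth classes.  Potencies are
# chosen so that effects at the Stage-II test concentration are essentially
# saturating (well above the generator noise floor).
COMPOUND_CLASSES = {
    "mutant_selective": lambda cid: DrugEffectModel(cid, {
        "sdh2": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.2),
        "wt": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.9),
        "nhp6a": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.9),
    }),
    "reference_selective": lambda cid: DrugEffectModel(cid, {
        "sdh2": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.9),
        "wt": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.2),
        "nhp6a": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.2),
    }),
    "nonselective_toxic": lambda cid: DrugEffectModel(cid, {
        "sdh2": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.3),
        "wt": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.3),
        "nhp6a": DrugEffect(ec50_um=1.0, hill=2.0, sat_mult=0.3),
    }),
}


def default_config(seed: int = 0) -> dict:
    """A complete, explicit run configuration (all thresholds spelled out)."""
    return {
        "seed": seed,
        "simulate": {
            "n_compounds": 320,
            "truth": {"mutant_selective": 12, "reference_selective": 2,
                      "nonselective_toxic": 6},
            "noise_sd": 0.01,
            "stage1_conc_um": 10.0,
            "stage2_conc_um": 50.0,
            "media_mix": 0.5,
        },
        "stage1": {"pi_threshold": 50.0, "read_time_h": 48.0},
        "stage2": {"delta_s": 0.3, "delta_r": 0.3, "delta_l": 0.5,
                   "mutant": "sdh2", "reference": "wt"},
        "stage3": {"marker": "nhp6a", "tolerance": 0.2},
    }


_REQUIRED_KEYS = {"seed", "simulate", "stage1", "stage2", "stage3"}


def _validate_config(config: dict) -> None:
    if missing := _REQUIRED_KEYS - set(config):
        raise ValueError(f"config missing sections: {sorted(missing)}")
    if "pi_threshold" not in config["stage1"]:
        raise ValueError("stage1.pi_threshold must be explicit")
    for k in ("delta_s", "delta_r", "delta_l"):
        if k not in config["stage2"]:
            raise ValueError(f"stage2.{k} threshold must be explicit")


def _assign_truth(n_compounds: int, truth_counts: dict, rng: np.random.Generator) -> dict[str, str]:
    """Map compound ids to effect classes; remaining compounds are inactive."""
    n_active = sum(truth_counts.values())
    if n_active > n_compounds:
        raise ValueError("more active compounds requested than compounds")
    chosen = rng.choice(n_compounds, size=n_active, replace=False)
    classes: dict[str, str] = {}
    i = 0
    for cls, count in truth_counts.items():
        for _ in range(count):
            classes[f"C{chosen[i] + 1:05d}"] = cls
            i += 1
    return classes


def run_screen(config: dict, outdir: str | Path) -> dict:
    """Execute the three-stage screen on synthetic data; write artifact tables.

    Returns the run manifest (also written to ``manifest.json``), including
    a funnel summary mirroring the screen's triage structure.
    """
    _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    timings: dict[str, float] = {}

    seed = int(config["seed"])
    sim = config["simulate"]
    rng = np.random.default_rng(seed)
    truth_classes = _assign_truth(sim["n_compounds"], sim["truth"], rng)

    # ---------------- Stage I: endpoint screen ----------------
    t0 = time.perf_counter()
    cfg = SimConfig(noise_sd=sim["noise_sd"], seed=seed, media_mix=sim["media_mix"])
    reads, plate_map = _apply_truth_to_plate(sim, cfg, truth_classes, seed)

    pi = summarize_plate(reads, plate_map)
    ctrl_reads, ctrl_map = gen_control_plate(replace(cfg, seed=seed + 1))
    qc = plate_qc(summarize_plate(ctrl_reads, ctrl_map))
    hits = call_hits(pi, threshold=config["stage1"]["pi_threshold"],
                     read_time_h=config["stage1"]["read_time_h"])
    hit_ids = sorted(hits["compound_id"].unique())
    timings["stage1_s"] = time.perf_counter() - t0

    # ---------------- Stage II: differential growth fits ----------------
    t0 = time.perf_counter()
    mutant = config["stage2"]["mutant"]
    reference = config["stage2"]["reference"]
    conc2 = sim["stage2_conc_um"]
    curve_cfg = SimConfig(noise_sd=sim["noise_sd"], media_mix=sim["media_mix"], seed=seed)
    fit_rows, curves = [], []
    for si, strain_name in enumerate((reference, mutant)):
        arch = _ARCHETYPES[strain_name]()
        cv = gen_growth_curve(arch, None, 0.0, replace(curve_cfg, seed=seed + 100 + si))
        curves.append(cv)
        fit_rows.append(_fit_row(cv, drug_present=False))
        for ci, cid in enumerate(hit_ids):
            model = COMPOUND_CLASSES[truth_classes[cid]](cid) if cid in truth_classes \
                else DrugEffectModel(cid, {})
            cvd = gen_growth_curve(
                arch, model, conc2,
                replace(curve_cfg, seed=seed + 1000 + 31 * ci + si),
            )
            curves.append(cvd)
            fit_rows.append(_fit_row(cvd, drug_present=True))
    fits = pd.DataFrame(fit_rows)
    thresholds = Thresholds(config["stage2"]["delta_s"], config["stage2"]["delta_r"],
                            config["stage2"]["delta_l"])
    scores = score_table(fits, mutant=mutant, reference=reference, thresholds=thresholds) \
        if hit_ids else pd.DataFrame(columns=["compound_id", "conc_um", "delta_s", "delta_r",
                                              "delta_l", "call", "any_selective"])
    timings["stage2_s"] = time.perf_counter() - t0

    # ---------------- Stage III: marker concordance ----------------
    t0 = time.perf_counter()
    selective = scores[scores["call"].isin(["mutant_selective", "reference_selective"])] \
        if not scores.empty else scores
    marker = config["stage3"]["marker"]
    concordance = pd.DataFrame()
    if not selective.empty:
        marker_rows = []
        arch = _ARCHETYPES[marker]()
        cvm = gen_growth_curve(arch, None, 0.0, replace(curve_cfg, seed=seed + 200))
        marker_rows.append(_fit_row(cvm, drug_present=False))
        for ci, cid in enumerate(sorted(selective["compound_id"].unique())):
            model = COMPOUND_CLASSES[truth_classes[cid]](cid) if cid in truth_classes \
                else DrugEffectModel(cid, {})
            cvd = gen_growth_curve(arch, model, conc2,
                                   replace(curve_cfg, seed=seed + 2000 + ci))
            marker_rows.append(_fit_row(cvd, drug_present=True))
        marker_fits = pd.DataFrame(marker_rows)
        ref_fits = fits[fits["strain"] == reference]
        sel_ids = set(selective["compound_id"])
        ref_sub = ref_fits[(~ref_fits["drug_present"]) | ref_fits["compound_id"].isin(sel_ids)]
        _, concordance = marker_concordance(ref_sub, marker_fits,
                                            tolerance=config["stage3"]["tolerance"])
    timings["stage3_s"] = time.perf_counter() - t0

    # ---------------- funnel + artifacts ----------------
    calls = scores.groupby("compound_id")["call"].agg(_compound_call) if not scores.empty \
        else pd.Series(dtype=object)
    n_mut = int((calls == "mutant_selective").sum())
    n_ref = int((calls == "reference_selective").sum())
    funnel = pd.DataFrame([
        {"count": sim["n_compounds"], "characteristic": "total compounds screened"},
        {"count": len(hit_ids),
         "characteristic": f"inhibit {mutant} at {sim['stage1_conc_um']:g} µM"},
        {"count": n_mut + n_ref, "characteristic": f"differential effect on {mutant} vs. {reference}"},
        {"count": n_mut, "characteristic": f"{mutant} inhibited more than {reference}"},
        {"count": n_ref, "characteristic": f"{reference} inhibited more than {mutant}"},
    ])

    truth_df = pd.DataFrame(
        [{"compound_id": cid, "class": cls} for cid, cls in sorted(truth_classes.items())]
    )
    artifacts = {
        "percent_inhibition.csv": pi,
        "qc_zfactor.csv": qc,
        "hits.csv": hits,
        "growth_fits.csv": fits,
        "differential_scores.csv": scores,
        "concordance.csv": concordance,
        "funnel.csv": funnel,
        "truth.csv": truth_df,
        "curves.csv": curves_to_frame(curves),
    }
    digests = {}
    for name, df in artifacts.items():
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {"sdhscreen": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "artifact_digests": digests,
        "timings_s": {**timings, "total_s": time.perf_counter() - t_start},
        "funnel": {r["characteristic"]: int(r["count"]) for _, r in funnel.iterrows()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _apply_truth_to_plate(sim: dict, cfg: SimConfig, truth_classes: dict[str, str], seed: int):
    """Stage-I plate where exactly the truth-class compounds are active."""
    def sampler(_rng, cid):
        return COMPOUND_CLASSES[truth_classes[cid]](cid)

    # hit_fraction=1 applies the sampler to every compound well; inactive
    # compounds get an empty effect model, so only truth compounds inhibit.
    def sampler_all(_rng, cid):
        if cid in truth_classes:
            return sampler(_rng, cid)
        return DrugEffectModel(cid, {})

    reads, plate_map, _ = gen_screen_plate(
        n_compounds=sim["n_compounds"],
        hit_fraction=1.0,
        effect_sampler=sampler_all,
        cfg=cfg,
        assay_conc_um=sim["stage1_conc_um"],
        allow_multiplate=True,
    )
    return reads, plate_map


def _fit_row(curve, drug_present: bool) -> dict:
    fit = fit_growth(curve.times_h, curve.od, n_phases="auto", random_state=0)
    from .differential import GrowthSummary

    s = GrowthSummary.from_fit(fit)
    return {
        "strain": curve.strain,
        "compound_id": curve.compound_id if curve.compound_id else "",
        "conc_um": curve.conc_um,
        "media_mix": curve.media_mix,
        "drug_present": drug_present,
        "n_phases": fit.n_phases,
        "saturation": s.saturation,
        "max_rate": s.max_rate,
        "lag_h": s.lag_h,
        "rss": fit.rss,
        "converged": s.converged,
    }


def _compound_call(calls: pd.Series) -> str:
    """Per-compound call across concentrations: selective at >= 1 concentration."""
    if (calls == "mutant_selective").any():
        return "mutant_selective"
    if (calls == "reference_selective").any():
        return "reference_selective"
    if (calls == "indeterminate").all():
        return "indeterminate"
    return "nonselective"


def report(outdir: str | Path, make_plots: bool = False) -> str:
    """Human-readable summary of a finished run's artifacts."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {outdir}")
    manifest = json.loads(manifest_path.read_text())

    lines = [f"sdhscreen run (seed {manifest['seed']})", "", "Screening funnel:"]
    for name, count in manifest["funnel"].items():
        lines.append(f"  {count:>8d}  {name}")

    qc_path = outdir / "qc_zfactor.csv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path)
        lines.append("")
        lines.append("Assay QC (z-factor per plate/read time):")
        for _, r in qc.iterrows():
            verdict = "OK for HTS" if r["suitable_for_hts"] else "NOT suitable"
            lines.append(f"  {r['plate_id']} @ {r['read_time_h']:.0f} h: "
                         f"z = {r['z_factor']:.3f} ({verdict})")

    scores_path = outdir / "differential_scores.csv"
    if scores_path.exists():
        scores = pd.read_csv(scores_path)
        sel = scores[scores["call"].isin(["mutant_selective", "reference_selective"])]
        lines.append("")
        if sel.empty:
            lines.append("No compounds advanced to Stage III (zero Stage-II selective calls).")
        else:
            lines.append("Selective compounds (delta scores; positive = mutant more inhibited):")
            for _, r in sel.iterrows():
                lines.append(
                    f"  {r['compound_id']} @ {r['conc_um']:g} µM: "
                    f"ΔS={r['delta_s']:+.2f} ΔR={r['delta_r']:+.2f} ΔL={r['delta_l']:+.2f}"
                    f" -> {r['call']}"
                )

    if make_plots:
        _plot_curves(outdir)
        lines.append("")
        lines.append(f"Growth-curve plot written to {outdir / 'curves.png'}")
    return "\n".join(lines)


def _plot_curves(outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = pd.read_csv(outdir / "curves.csv")
    fig, ax = plt.subplots(figsize=(7, 4))
    for (strain, cid, conc), grp in curves.groupby(["strain", "compound_id", "conc_um"], dropna=False):
        label = f"{strain}" + (f" + {cid} {conc:g}µM" if isinstance(cid, str) and cid else "")
        ax.plot(grp["time_h"], grp["od600"], lw=0.8, label=label)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("OD600")
    if len(ax.lines) <= 12:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "curves.png", dpi=120)
    plt.close(fig)
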