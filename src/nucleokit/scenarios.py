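"""End-to-end packaged scenarios: simulate → calibrate → quantify → kinetics.

Each scenario reproduces the structure of one of the assay's experiments —
a DNase I titration, ExoIII 3'-overhang series, T7 Exo 5'-overhang series,
mismatch and methylation comparisons, nick/gap/nickase coupling, Trex2
ssDNA digestion, Klenow primer extension, and the RNase A / RNase H RNA-dye
assays — runs the full analysis pipeline on the simulated plate, and
summarises recovered rates.  A scenario is fully reproducible from its
name + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .calibrate import fit_standard_curve
from .kinetics import (
    compare_conditions,
    completion_time,
    max_gradient,
    per_nM_rate,
    tukey_p,
)
from .library import builtin_substrates, enzyme_for_simulation
from .quantify import convert_plate
from .simulate import DyeModel, LadderSpec, PlateRun, SimConfig, make_ladder, simulate_plate

__all__ = ["SCENARIOS", "ScenarioReport", "run_scenario", "run_pipeline", "titration_per_nM"]

_DT = 45.0
_DUR = 3600.0
_QI_DYE = DyeModel(mode="QI_RNA", ss_fraction=0.05)


@dataclass
class ScenarioReport:
    name: str
    seed: int | None
    plate: PlateRun
    curve: object
    curves: dict
    rates: pd.DataFrame
    summary: dict
    qc: dict = field(default_factory=dict)


def run_pipeline(plate: PlateRun, window_points: int = 5, normalize: bool = True):
    """Calibrate, normalise, convert and extract rates for a whole plate."""
    curve = fit_standard_curve(plate, normalize=normalize)
    curves = convert_plate(plate, curve, normalize=normalize)
    rows = []
    for well, rc in curves.items():
        est = max_gradient(rc, window_points=window_points)
        role = rc.meta.get("role", "sample")
        ct = completion_time(rc) if role == "sample" else None
        rows.append(
            {
                "well": well,
                "role": role,
                "group": rc.meta.get("replicate_group", ""),
                "substrate": rc.meta.get("substrate", ""),
                "enzyme": rc.meta.get("enzyme", ""),
                "enzyme_conc_nM": float(rc.meta.get("enzyme_conc_nM", 0.0)),
                "replicate": int(rc.meta.get("replicate", 0)),
                "max_gradient": est.max_gradient,
                "sign": est.sign,
                "per_nM_rate": est.per_nM_rate,
                "completion_time_s": ct,
                "window_start_s": est.window[0],
                "window_end_s": est.window[1],
            }
        )
    rates = pd.DataFrame(rows).sort_values(["role", "group", "replicate"]).reset_index(drop=True)
    return curve, curves, rates


def titration_per_nM(rates: pd.DataFrame, substrate: str, enzyme: str | None = None):
    """Per-nM rate from a concentration titration on one substrate.

    Sample max gradients are grouped by enzyme concentration; the matched
    no-enzyme controls on the same substrate enter at concentration 0.
    """
    samp = rates[(rates["role"] == "sample") & (rates["substrate"] == substrate)]
    if enzyme is not None:
        samp = samp[samp["enzyme"] == enzyme]
    by_conc: dict[float, list] = {}
    for conc, grp in samp.groupby("enzyme_conc_nM"):
        by_conc[float(conc)] = list(grp["max_gradient"])
    ctrl = rates[(rates["role"] == "control") & (rates["substrate"] == substrate)]
    if not ctrl.empty:
        by_conc[0.0] = list(ctrl["max_gradient"])
    return per_nM_rate(by_conc)


def _group_rate(rates: pd.DataFrame, substrate: str, conc: float | None = None) -> float:
    s = rates[(rates["role"] == "sample") & (rates["substrate"] == substrate)]
    if conc is not None:
        s = s[np.isclose(s["enzyme_conc_nM"], conc)]
    return float(s["max_gradient"].mean())


def _group_values(rates: pd.DataFrame, substrate: str, conc: float | None = None) -> list:
    s = rates[(rates["role"] == "sample") & (rates["substrate"] == substrate)]
    if conc is not None:
        s = s[np.isclose(s["enzyme_conc_nM"], conc)]
    return list(s["max_gradient"])


# ---------------------------------------------------------------------------
# scenario builders


def _cfgs(substrate_names, enzyme, concs, *, dye=None, dt=_DT, dur=_DUR, n_rep=3, **kw):
    subs = builtin_substrates()
    dye = dye or DyeModel()
    out = []
    for name in substrate_names:
        for conc in concs:
            out.append(
                SimConfig(
                    substrate=subs[name],
                    enzyme=enzyme,
                    enzyme_conc=conc,
                    dye=dye,
                    sampling_interval_s=dt,
                    duration_s=dur,
                    n_replicates=n_rep,
                    label=f"{enzyme.name if enzyme else 'none'}|{name}|{conc:g}nM",
                    **kw,
                )
            )
    return out


def _sc_dnase_titration(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("DNase I")
    cfgs = _cfgs(["S_blunt"], enz, [2.0, 4.0, 8.0, 16.0], dur=dur, n_rep=n_rep)
    ladder = make_ladder("dnase", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        pr = titration_per_nM(rates, "S_blunt", "DNase I")
        return {
            "per_nM_rate_bp_nM_s": pr.rate,
            "first_order_r2": pr.r_squared,
            "standard_curve_r2_t0": float(curve.r_squared[0]),
        }

    return cfgs, ladder, 11, summarize


def _sc_exoiii_titration(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("ExoIII")
    cfgs = _cfgs(["S_b3"], enz, [2.0, 5.0, 10.0], dur=dur, n_rep=n_rep)
    ladder = make_ladder("resection", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        pr = titration_per_nM(rates, "S_b3", "ExoIII")
        return {"per_nM_rate_bp_nM_s": pr.rate, "first_order_r2": pr.r_squared}

    return cfgs, ladder, 7, summarize


def _sc_exoiii_overhangs(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("ExoIII")
    names = ["S_b3", "S_b3_ovh2", "S_b3_ovh4", "S_b3b3"]
    cfgs = _cfgs(names, enz, [10.0], dur=dur, n_rep=n_rep)
    ladder = make_ladder("resection", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        blunt = _group_rate(rates, "S_b3")
        out = {"rate_blunt": blunt}
        for n, key in [("S_b3_ovh2", "pct_2nt"), ("S_b3_ovh4", "pct_4nt"), ("S_b3b3", "pct_blocked")]:
            out[key] = 100.0 * _group_rate(rates, n) / blunt if blunt else float("nan")
        return out

    return cfgs, ladder, 7, summarize


def _sc_t7_overhangs(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("T7 Exo")
    names = ["S_b5", "S_b5_ovh2", "S_b5_ovh10", "S_b5_ovh20", "S_b5b5"]
    cfgs = _cfgs(names, enz, [12.0], dur=dur, n_rep=n_rep)
    ladder = make_ladder("resection", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        blunt = _group_rate(rates, "S_b5")
        out = {"rate_blunt": blunt}
        for n, key in [
            ("S_b5_ovh2", "pct_2nt"),
            ("S_b5_ovh10", "pct_10nt"),
            ("S_b5_ovh20", "pct_20nt"),
            ("S_b5b5", "pct_blocked"),
        ]:
            out[key] = 100.0 * _group_rate(rates, n) / blunt if blunt else float("nan")
        return out

    return cfgs, ladder, 7, summarize


def _sc_mismatches(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("ExoIII")
    names = ["S_b3", "S_b3_mmAC", "S_b3_mmTG"]
    cfgs = _cfgs(names, enz, [5.0, 10.0], dur=dur, n_rep=n_rep)
    ladder = make_ladder("resection", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        out = {}
        for conc in (5.0, 10.0):
            m = _group_rate(rates, "S_b3", conc)
            out[f"fold_AC_{conc:g}nM"] = _group_rate(rates, "S_b3_mmAC", conc) / m
            out[f"fold_TG_{conc:g}nM"] = _group_rate(rates, "S_b3_mmTG", conc) / m
        groups = {
            "matched": _group_values(rates, "S_b3", 10.0),
            "mmAC": _group_values(rates, "S_b3_mmAC", 10.0),
            "mmTG": _group_values(rates, "S_b3_mmTG", 10.0),
        }
        comp = compare_conditions(groups)
        out["anova_p"] = comp.anova_p
        out["tukey_p_matched_vs_mmAC_10nM"] = tukey_p(("matched", "mmAC"), comp)
        return out

    return cfgs, ladder, 7, summarize


def _sc_methylation(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("ExoIII")
    names = ["S_b3", "S_b3_1M", "S_b3_4M"]
    cfgs = _cfgs(names, enz, [5.0, 10.0], dur=dur, n_rep=n_rep)
    ladder = make_ladder("resection", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        out = {}
        samp = rates[rates["role"] == "sample"]
        for conc in (5.0, 10.0):
            for n in names:
                sel = samp[(samp["substrate"] == n) & np.isclose(samp["enzyme_conc_nM"], conc)]
                ct = sel["completion_time_s"].dropna()
                out[f"completion_{n}_{conc:g}nM"] = float(ct.mean()) if len(ct) else None
                out[f"rate_{n}_{conc:g}nM"] = float(sel["max_gradient"].mean())
        return out

    return cfgs, ladder, 7, summarize


def _sc_nickase_coupling(n_rep=3, dur=_DUR):
    exo = enzyme_for_simulation("ExoIII")
    nick = enzyme_for_simulation("Nt.CviPII")
    base = _cfgs(["S_b3b3", "S_b3b3_nick", "S_b3b3_gap"], exo, [40.0], dur=dur, n_rep=n_rep)
    subs = builtin_substrates()
    coupled = SimConfig(
        substrate=subs["S_b3b3_motifs"],
        enzyme=exo,
        enzyme_conc=40.0,
        nickase=nick,
        nickase_conc=10.0,
        sampling_interval_s=_DT,
        duration_s=dur,
        n_replicates=n_rep,
        label="ExoIII+Nt.CviPII|S_b3b3_motifs|40nM",
    )
    nickase_only = SimConfig(
        substrate=subs["S_b3b3_motifs"],
        enzyme=None,
        enzyme_conc=0.0,
        nickase=nick,
        nickase_conc=10.0,
        sampling_interval_s=_DT,
        duration_s=dur,
        n_replicates=n_rep,
        label="Nt.CviPII|S_b3b3_motifs|10nM",
    )
    ladder = make_ladder("resection", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        return {
            "rate_blocked": _group_rate(rates, "S_b3b3"),
            "rate_nick": _group_rate(rates, "S_b3b3_nick"),
            "rate_gap": _group_rate(rates, "S_b3b3_gap"),
            "rate_coupled": float(
                rates[(rates["group"] == "ExoIII+Nt.CviPII|S_b3b3_motifs|40nM")]["max_gradient"].mean()
            ),
            "rate_nickase_only": float(
                rates[(rates["group"] == "Nt.CviPII|S_b3b3_motifs|10nM")]["max_gradient"].mean()
            ),
        }

    return base + [coupled, nickase_only], ladder, 7, summarize


def _sc_trex2_ss(n_rep=3, dur=3000.0):
    enz = enzyme_for_simulation("Trex2")
    cfgs = _cfgs(["ss20", "ss40", "ss60"], enz, [100.0, 200.0], dur=dur, n_rep=n_rep)
    ladder = make_ladder("ss", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        out = {}
        samp = rates[rates["role"] == "sample"]
        for n in ("ss20", "ss40", "ss60"):
            sel = samp[samp["substrate"] == n]
            out[f"per_nM_{n}"] = float((sel["max_gradient"] / sel["enzyme_conc_nM"]).mean())
        return out

    return cfgs, ladder, 5, summarize


def _sc_klenow(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("Klenow")
    cfgs = _cfgs(
        ["pt_primer20", "pt_primer40", "pt_primer60"],
        enz,
        [1.0],
        dur=dur,
        n_rep=n_rep,
        polymerase_hard_stop=52,
    )
    ladder = make_ladder("resection", n_replicates=n_rep)

    def summarize(rates, curve, curves):
        # substrate naming is by primer length; the template overhang is 80-p
        r20 = _group_rate(rates, "pt_primer60")  # 20-nt overhang
        r40 = _group_rate(rates, "pt_primer40")  # 40-nt overhang
        r60 = _group_rate(rates, "pt_primer20")  # 60-nt overhang
        return {
            "rate_overhang20": r20,
            "rate_overhang40": r40,
            "rate_overhang60": r60,
            "ratio_60_vs_short": r60 / np.mean([r20, r40]),
        }

    return cfgs, ladder, 7, summarize


def _sc_rnase_a(n_rep=3, dur=2400.0):
    enz = enzyme_for_simulation("RNase A")
    conc = 3.64e-4
    c20 = _cfgs(["rna20"], enz, [conc], dye=_QI_DYE, dt=40.0, dur=dur, n_rep=n_rep)
    # the 40-mer digests at about half the 20-mer per-nM rate
    c40 = _cfgs(["rna40"], enz, [conc], dye=_QI_DYE, dt=40.0, dur=dur, n_rep=n_rep, rate_scale=0.5)
    ladder = make_ladder("rna", lengths=(40, 30, 20, 10), n_replicates=n_rep)

    def summarize(rates, curve, curves):
        samp = rates[rates["role"] == "sample"]
        out = {}
        for n in ("rna20", "rna40"):
            sel = samp[samp["substrate"] == n]
            out[f"per_nM_{n}"] = float((sel["max_gradient"] / sel["enzyme_conc_nM"]).mean())
        return out

    return c20 + c40, ladder, 5, summarize


def _sc_rnase_h(n_rep=3, dur=_DUR):
    enz = enzyme_for_simulation("RNase H")
    cfgs = _cfgs(["hybrid20", "hybrid40"], enz, [280.0], dye=_QI_DYE, dur=dur, n_rep=n_rep)
    ladder = make_ladder("hybrid", lengths=(40, 30, 20, 10), n_replicates=n_rep)

    def summarize(rates, curve, curves):
        samp = rates[rates["role"] == "sample"]
        out = {}
        for n in ("hybrid20", "hybrid40"):
            sel = samp[samp["substrate"] == n]
            out[f"per_nM_{n}"] = float((sel["max_gradient"] / sel["enzyme_conc_nM"]).mean())
        return out

    return cfgs, ladder, 9, summarize


SCENARIOS = {
    "dnase_titration": _sc_dnase_titration,
    "exoiii_titration": _sc_exoiii_titration,
    "exoiii_overhangs": _sc_exoiii_overhangs,
    "t7_overhangs": _sc_t7_overhangs,
    "mismatches": _sc_mismatches,
    "methylation": _sc_methylation,
    "nickase_coupling": _sc_nickase_coupling,
    "trex2_ss": _sc_trex2_ss,
    "klenow": _sc_klenow,
    "rnase_a": _sc_rnase_a,
    "rnase_h": _sc_rnase_h,
}


def run_scenario(
    name: str, seed: int | None = 0, outdir=None, plot: bool = False, **overrides
) -> ScenarioReport:
    """Run a packaged scenario end-to-end; deterministic given seed.

    ``overrides`` are forwarded to the scenario builder (e.g. ``n_rep``,
    ``dur``) for scaled-down runs.  With ``outdir``, writes plate.csv,
    map.csv, curve.json, curves.csv, rates.csv and report.json; ``plot``
    additionally writes curves.png (converted progress curves per group).
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    cfgs, ladder, window, summarize = SCENARIOS[name](**overrides)
    plate = simulate_plate(cfgs, ladder, seed=seed)
    curve, curves, rates = run_pipeline(plate, window_points=window)
    summary = summarize(rates, curve, curves)
    qc = {
        "flagged_curve_timepoints": int(curve.flagged.size),
        "dropped_timepoints": int(sum(rc.dropped_timepoints for rc in curves.values())),
        "n_wells": int(plate.wellmap.shape[0]),
        "window_points": window,
    }
    report = ScenarioReport(name, seed, plate, curve, curves, rates, summary, qc)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_plate(plate, outdir / "plate.csv", outdir / "map.csv")
        nio.write_curve(curve, outdir / "curve.json")
        nio.write_curves_long(curves, outdir / "curves.csv")
        rates.to_csv(outdir / "rates.csv", index=False, float_format="%.6g")
        payload = {
            "scenario": name,
            "seed": seed,
            "summary": _jsonable(summary),
            "qc": _jsonable(qc),
        }
        (outdir / "report.json").write_text(json.dumps(payload, indent=1))
        if plot:
            _plot_curves(curves, outdir / "curves.png", title=name)
    return report


def _plot_curves(curves: dict, path, title: str = "") -> None:
    """Converted progress curves, one colour per replicate group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    groups = sorted({rc.meta.get("replicate_group", "") for rc in curves.values()})
    cmap = plt.get_cmap("tab10")
    color = {g: cmap(i % 10) for i, g in enumerate(groups)}
    seen = set()
    for rc in curves.values():
        g = rc.meta.get("replicate_group", "")
        ax.plot(
            rc.time_s,
            rc.length_bp,
            color=color[g],
            alpha=0.8,
            label=g if g not in seen else None,
        )
        seen.add(g)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("remaining length (bp / nt)")
    ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, float) and not np.isfinite(v):
            v = None
        out[str(k)] = v
    return out
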