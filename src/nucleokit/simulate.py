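"""Mechanistic plate simulator for real-time fluorescence nuclease assays.

Generates plate-reader fluorescence time series with the kinetic and
statistical structure the analysis pipeline assumes: a per-molecule
continuous-time simulation of directional resection fronts, distributive
cleavage, nickase-coupled resection, primer extension and single-strand
digestion, rendered through a dye model (intercalating dsDNA dye or an
RNA-sensitive dye) with shared photobleaching, signal saturation and
Gaussian read noise.

Trajectories report two population-mean lengths per timepoint:

``primary_nt``
    the species the dye reads at full weight — duplex bp for the dsDNA dye,
    RNA nt for the RNA dye;
``secondary_nt``
    the species read at reduced weight ``ss_fraction`` — single-stranded
    DNA (overhangs, exposed tracts, ss substrates) for the dsDNA dye,
    exposed ssDNA for the RNA dye.

For double-stranded DNA modes ``primary_nt`` is exactly the remaining
duplex length L_ds(t) and ``secondary_nt`` the single-strand content
L_ss(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .substrates import (
    EnzymeSpec,
    InitiationSite,
    SubstrateSpec,
    accessible_ends,
    _internal_entry,
    DA_PER_BP_DS,
    DA_PER_NT_SS,
)

__all__ = [
    "DyeModel",
    "SimConfig",
    "Trajectory",
    "PlateRun",
    "LadderSpec",
    "ConfigurationError",
    "simulate_progress",
    "render_fluorescence",
    "simulate_plate",
    "make_ladder",
    "static_signal_lengths",
]

#: default read noise as a fraction of the clean t=0 signal of each well
DEFAULT_NOISE_CV = 0.003

_END_OWNER = {"top5": "top", "top3": "top", "bot5": "bottom", "bot3": "bottom"}
_LEFT_TERMINUS = ("top5", "bot3")
_RIGHT_TERMINUS = ("top3", "bot5")


class ConfigurationError(ValueError):
    """Raised when a plate/run specification is incomplete."""


@dataclass(frozen=True)
class DyeModel:
    """Fluorescent dye read-out model.

    ``alpha_ds`` — fluorescence units per primary nt per nM substrate;
    ``ss_fraction`` — relative signal of the secondary (single-stranded)
    species; ``background`` — free-dye signal; ``enhancement_fold`` —
    bound/free intensity ratio (informational; the rendered signal is
    parameterised by ``alpha_ds`` and ``background`` directly);
    ``saturation_mass`` — ng/µL above which the signal plateaus;
    ``bleach_rate`` — shared photobleaching rate constant (s^-1);
    ``mode`` — "PG_dsDNA" or "QI_RNA".
    """

    alpha_ds: float = 0.25
    ss_fraction: float = 0.10
    background: float = 2.5
    enhancement_fold: float = 400.0
    saturation_mass: float = 2.5
    bleach_rate: float = 1e-4
    mode: str = "PG_dsDNA"

    def __post_init__(self):
        if not 0 <= self.ss_fraction < 1:
            raise ConfigurationError("ss_fraction must be in [0, 1)")
        if not self.saturation_mass > 0:
            raise ConfigurationError("saturation_mass must be > 0")
        if self.bleach_rate < 0:
            raise ConfigurationError("bleach_rate must be >= 0")
        if self.mode not in ("PG_dsDNA", "QI_RNA"):
            raise ConfigurationError(f"unknown dye mode {self.mode!r}")

    def saturate(self, mass: np.ndarray) -> np.ndarray:
        """Smooth hyperbolic clip: identity below ``saturation_mass``,
        plateauing to 1.5× the cap above it."""
        s = self.saturation_mass
        w = 0.5 * s
        m = np.asarray(mass, dtype=float)
        return np.where(m <= s, m, s + w * np.tanh((m - s) / w))


@dataclass(frozen=True)
class SimConfig:
    """One simulated condition: substrate × enzyme × concentration.

    ``purity`` is the probability that each *blocked strand* was synthesised
    full-length with its biotin-TEG modification; molecules missing a block
    expose that end to initiation.  ``protected_window_nt`` is the terminal
    window streptavidin shields from an approaching front.  ``noise_sd`` of
    None selects read noise of ``DEFAULT_NOISE_CV`` × clean t0 signal.
    ``deterministic`` switches to the N→∞ mean-field limit (exact mean
    waiting times, purity cases combined by probability weight).
    """

    substrate: SubstrateSpec
    enzyme: EnzymeSpec | None = None
    enzyme_conc: float = 0.0
    substrate_conc: float = 50.0
    duration_s: float = 3600.0
    sampling_interval_s: float = 45.0
    n_replicates: int = 3
    seed: int | None = None
    purity: float = 0.85
    protected_window_nt: int = 20
    dye: DyeModel = field(default_factory=DyeModel)
    noise_sd: float | None = None
    n_molecules: int = 2000
    deterministic: bool = False
    nickase: EnzymeSpec | None = None
    nickase_conc: float = 0.0
    polymerase_hard_stop: int | None = None
    rate_scale: float = 1.0
    delay_ref_nM: float = 5.0
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.purity <= 1:
            raise ConfigurationError("purity must be in [0, 1]")
        if not self.sampling_interval_s > 0:
            raise ConfigurationError("sampling_interval_s must be > 0")
        if self.enzyme is not None and self.enzyme_conc < 0:
            raise ConfigurationError("enzyme_conc must be >= 0")
        if self.n_molecules < 1:
            raise ConfigurationError("n_molecules must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 0.5 * self.sampling_interval_s, self.sampling_interval_s)


@dataclass
class Trajectory:
    """Per-replicate population-mean progress curves."""

    time_s: np.ndarray
    primary_nt: np.ndarray  # (n_rep, n_t)
    secondary_nt: np.ndarray  # (n_rep, n_t)
    substrate: SubstrateSpec
    mode: str
    molecules: list | None = None  # optional per-molecule resolve data


@dataclass
class LadderSpec:
    """Standard-ladder description: (substrate, assigned length) members."""

    members: list  # [(SubstrateSpec, float length value)]
    conc_nM: float = 50.0
    n_replicates: int = 3


@dataclass
class PlateRun:
    """A simulated (or loaded) plate: time × well matrix plus well map."""

    data: pd.DataFrame  # index time_s, one column per well
    wellmap: pd.DataFrame
    substrates: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# static (no-enzyme) signal lengths


def static_signal_lengths(substrate: SubstrateSpec, dye_mode: str = "PG_dsDNA") -> tuple[float, float]:
    """(primary, secondary) nt of an untouched substrate under a dye mode."""
    s = substrate
    if s.is_primer_template:
        duplex = s.primer_length
        ss = (s.duplex_length - s.primer_length) + s.total_overhang_nt
    else:
        duplex = s.duplex_length
        ss = s.total_overhang_nt + s.ss_length
        gap_nt = sum(g[2] for g in s.gaps)
        duplex -= gap_nt
        ss += gap_nt
    if dye_mode == "PG_dsDNA":
        return float(duplex), float(ss)
    # QI_RNA: RNA species read at full weight, ssDNA at reduced weight
    if s.nucleic_kind == "ssRNA":
        return float(s.ss_length), 0.0
    if s.nucleic_kind in ("dsRNA", "RNA_DNA_hybrid"):
        return float(s.duplex_length), 0.0
    # DNA species under the RNA dye: weak signal only
    return 0.0, float(duplex + ss)


# ---------------------------------------------------------------------------
# core per-molecule engines


def _exp_draws(rng, mean, size, deterministic):
    if deterministic:
        return np.full(size, mean)
    return rng.exponential(mean, size=size)


def _front_stop_count(entry: int, direction: int, L: int, target_blocked: bool, pw: int) -> int:
    """How many duplex nt a front may resect before halting."""
    if direction < 0:
        lo = pw if target_blocked else 0
        return max(0, entry - lo + 1)
    hi = L - 1 - (pw if target_blocked else 0)
    return max(0, hi - entry + 1)


def _terminus_blocked(direction: int, eff_blocked: frozenset) -> bool:
    ends = _LEFT_TERMINUS if direction < 0 else _RIGHT_TERMINUS
    return any(e in eff_blocked for e in ends)


def _simulate_duplex_resection(cfg: SimConfig, rng, return_molecules: bool):
    """Directional exonuclease (and optional coupled nickase) on a duplex."""
    sub, enz = cfg.substrate, cfg.enzyme
    L = sub.duplex_length
    times = cfg.times
    n_t = times.size
    pw = cfg.protected_window_nt
    les_mult = {"top": sub.lesion_multipliers("top"), "bottom": sub.lesion_multipliers("bottom")}

    # which strands carry blocks (purity applies per blocked strand)
    blocked_strands = sorted({_END_OWNER[e] for e in sub.blocked_ends})

    if cfg.deterministic:
        cases, weights, n_per_case = _purity_cases(blocked_strands, cfg.purity, None)
        n_mol_case = [1] * len(cases)
    else:
        cases, weights, n_per_case = _purity_cases(blocked_strands, cfg.purity, (rng, cfg.n_molecules))
        n_mol_case = n_per_case

    prim = np.zeros(n_t)
    sec = np.zeros(n_t)
    total_w = 0.0
    molecules = [] if return_molecules else None

    for case, w, g in zip(cases, weights, n_mol_case):
        if g == 0 or w == 0.0:
            continue
        eff_blocked = frozenset(e for e in sub.blocked_ends if case.get(_END_OWNER[e], True))
        R = {
            "top": np.full((g, L), np.inf),
            "bottom": np.full((g, L), np.inf),
        }
        # gaps pre-resected on all molecules
        for strand, start, length in sub.gaps:
            if strand == "top":
                lo = sub.nick_duplex_coord(strand, start)
            else:
                lo = sub.nick_duplex_coord(strand, start + length)
            R[strand][:, max(0, lo) : min(L, lo + length)] = -1.0
        overhang_records = []  # (arrivals (g, v),) preludes consumed by fronts

        sites = []
        if enz is not None and cfg.enzyme_conc > 0:
            sites = accessible_ends(sub, enz, eff_blocked)
        t_start0 = np.zeros(g)
        delay = sub.methyl_delay_s
        if delay > 0 and sites and cfg.enzyme_conc > 0:
            mean = delay * cfg.delay_ref_nM / cfg.enzyme_conc
            t_start0 = _exp_draws(rng, mean, g, cfg.deterministic)

        for site in sites:
            _run_front(
                cfg, rng, site, R, overhang_records, t_start0, g, eff_blocked, les_mult
            )

        # coupled nickase: nicks appear at motif sites, then the exonuclease
        # initiates from each nick once it exists
        if cfg.nickase is not None and cfg.nickase_conc > 0 and enz is not None and cfg.enzyme_conc > 0:
            nick_sites = accessible_ends(sub, cfg.nickase, eff_blocked)
            for ns in nick_sites:
                t_nick = _exp_draws(
                    rng, 1.0 / (ns.multiplier * cfg.nickase_conc), g, cfg.deterministic
                )
                entry, direction = _internal_entry(enz.directionality, ns.strand, ns.entry)
                if not 0 <= entry < L:
                    continue
                fsite = InitiationSite(
                    kind="nick",
                    site_id=f"nickase_{ns.site_id}",
                    strand=ns.strand,
                    entry=entry,
                    direction=direction,
                    multiplier=float(enz.site_multipliers.get("nick", 1.0)),
                )
                _run_front(cfg, rng, fsite, R, overhang_records, t_nick, g, eff_blocked, les_mult)

        static_over = float(sub.total_overhang_nt)
        for k in range(n_t):
            t = times[k]
            it = R["top"] > t
            ib = R["bottom"] > t
            prim_k = (it & ib).sum() / g
            sec_k = (it ^ ib).sum() / g
            over_k = static_over
            for arr in overhang_records:
                over_k -= (arr <= t).sum() / g
            prim[k] += w * prim_k
            sec[k] += w * (sec_k + over_k)
        total_w += w
        if return_molecules:
            molecules.append({"weight": w, "R_top": R["top"], "R_bottom": R["bottom"]})

    if total_w == 0:
        p0, s0 = static_signal_lengths(sub, cfg.dye.mode)
        return np.full(n_t, p0), np.full(n_t, s0), molecules
    return prim / total_w, sec / total_w, molecules


def _purity_cases(blocked_strands, purity, draw):
    """Enumerate strand-intactness cases.

    Returns (cases, weights, counts): each case maps strand -> intact bool.
    With ``draw`` = (rng, n_mol), counts are multinomial draws; without,
    counts are None and weights are exact probabilities (mean-field).
    """
    if not blocked_strands:
        if draw is None:
            return [dict()], [1.0], None
        return [dict()], [1.0], [draw[1]]
    k = len(blocked_strands)
    cases, probs = [], []
    for bits in range(2**k):
        case = {s: bool((bits >> i) & 1) for i, s in enumerate(blocked_strands)}
        p = 1.0
        for s in blocked_strands:
            p *= purity if case[s] else (1 - purity)
        cases.append(case)
        probs.append(p)
    if draw is None:
        return cases, probs, None
    rng, n_mol = draw
    counts = rng.multinomial(n_mol, probs)
    weights = [c / n_mol for c in counts]
    return cases, weights, list(counts)


def _run_front(cfg, rng, site, R, overhang_records, t_start, g, eff_blocked, les_mult):
    """Advance one resection front; writes per-position resolve times."""
    sub, enz = cfg.substrate, cfg.enzyme
    L = sub.duplex_length
    h = enz.base_rate * cfg.enzyme_conc * site.multiplier * cfg.rate_scale
    if h <= 0:
        return
    t0 = np.asarray(t_start, dtype=float).copy()
    if t0.shape == ():
        t0 = np.full(g, float(t0))
    # single-stranded prelude (the front's own overhang)
    if site.overhang_nt > 0:
        waits = _exp_draws(rng, 1.0 / h, (g, site.overhang_nt), cfg.deterministic)
        arr = t0[:, None] + np.cumsum(waits, axis=1)
        overhang_records.append(arr)
        t0 = arr[:, -1].copy()
    blocked_target = _terminus_blocked(site.direction, eff_blocked)
    n_max = _front_stop_count(site.entry, site.direction, L, blocked_target, cfg.protected_window_nt)
    if n_max <= 0:
        return
    coords = site.entry + site.direction * np.arange(n_max)
    mult = les_mult[site.strand][coords]
    waits = _exp_draws(rng, 1.0, (g, n_max), cfg.deterministic) / (h * mult)[None, :]
    arrivals = t0[:, None] + np.cumsum(waits, axis=1)
    # coords are unique within one front, so a vectorised min-update is safe
    strand_R = R[site.strand]
    strand_R[:, coords] = np.minimum(strand_R[:, coords], arrivals)


def _simulate_distributive(cfg: SimConfig, rng, return_molecules: bool):
    """Per-position cleavage with uniform hazard (DNase-like, RNase H)."""
    sub, enz = cfg.substrate, cfg.enzyme
    L = sub.duplex_length if sub.duplex_length > 0 else sub.ss_length
    times = cfg.times
    hazard = enz.base_rate * cfg.enzyme_conc * cfg.rate_scale
    n = 1 if cfg.deterministic else cfg.n_molecules
    Rm = None
    if hazard <= 0:
        prim = np.full(times.size, float(L))
    elif cfg.deterministic:
        prim = L * np.exp(-hazard * times)
    else:
        Rm = rng.exponential(1.0 / hazard, size=(n, L))
        prim = np.array([(Rm > t).sum() / n for t in times])
    if enz.directionality == "rna_hybrid":
        sec = L - prim  # exposed ssDNA strand of the hybrid
    else:
        sec = np.zeros_like(prim)
    mol = [{"R": Rm}] if (return_molecules and Rm is not None) else None
    return prim, sec, mol


def _simulate_ss(cfg: SimConfig, rng, return_molecules: bool):
    """Processive digestion of a single strand from its attacked terminus."""
    sub, enz = cfg.substrate, cfg.enzyme
    n_nt = sub.ss_length
    times = cfg.times
    sites = accessible_ends(sub, enz)
    if not sites or cfg.enzyme_conc <= 0:
        return np.full(times.size, float(n_nt)), np.zeros(times.size), None
    h = enz.base_rate * cfg.enzyme_conc * cfg.rate_scale
    mult = sub.lesion_multipliers("top")[:n_nt] if n_nt else np.ones(0)
    n = 1 if cfg.deterministic else cfg.n_molecules
    waits = _exp_draws(rng, 1.0, (n, n_nt), cfg.deterministic) / (h * mult[::-1])[None, :]
    arrivals = np.cumsum(waits, axis=1)
    remaining = np.array([(arrivals > t).sum() / n for t in times])
    mol = [{"arrivals": arrivals}] if return_molecules else None
    return remaining, np.zeros_like(remaining), mol


def _simulate_polymerase(cfg: SimConfig, rng, return_molecules: bool):
    """Primer extension: duplex grows from the primer 3' terminus."""
    sub, enz = cfg.substrate, cfg.enzyme
    L, p = sub.duplex_length, sub.primer_length
    times = cfg.times
    template_ss = L - p
    stop = L
    if cfg.polymerase_hard_stop is not None and p < cfg.polymerase_hard_stop:
        stop = min(L, cfg.polymerase_hard_stop)
    mult = enz.overhang_rate_attenuation.get(template_ss, 1.0)
    h = enz.base_rate * cfg.enzyme_conc * mult * cfg.rate_scale
    n_ext = max(0, stop - p)
    n = 1 if cfg.deterministic else cfg.n_molecules
    if h <= 0 or n_ext == 0:
        duplex = np.full(times.size, float(p))
    else:
        waits = _exp_draws(rng, 1.0 / h, (n, n_ext), cfg.deterministic)
        arrivals = np.cumsum(waits, axis=1)
        duplex = np.array([p + (arrivals <= t).sum() / n for t in times])
    sec = (L - duplex) + sub.total_overhang_nt
    return duplex, sec, None


# ---------------------------------------------------------------------------
# public simulation API


def simulate_progress(
    config: SimConfig, rng: np.random.Generator | None = None, return_molecules: bool = False
) -> Trajectory:
    """Simulate per-replicate population-mean progress curves.

    With ``enzyme=None`` (or no accessible initiation site) the trajectory
    is flat — the negative-control phenotype.  Each replicate is an
    independent molecule population.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sub = config.substrate
    times = config.times
    n_rep = config.n_replicates
    mode = _mode_of(config)

    prim = np.zeros((n_rep, times.size))
    sec = np.zeros((n_rep, times.size))
    mols = [] if return_molecules else None
    for r in range(n_rep):
        if mode == "flat":
            p0, s0 = static_signal_lengths(sub, config.dye.mode)
            pr, se, mo = np.full(times.size, p0), np.full(times.size, s0), None
        elif mode == "resection":
            pr, se, mo = _simulate_duplex_resection(config, rng, return_molecules)
            if config.dye.mode == "QI_RNA":
                pr, se = _qi_reassign(sub, pr, se)
        elif mode == "distributive":
            pr, se, mo = _simulate_distributive(config, rng, return_molecules)
            if config.dye.mode == "PG_dsDNA" and sub.nucleic_kind == "RNA_DNA_hybrid":
                pr, se = se, pr
        elif mode == "ss":
            pr, se, mo = _simulate_ss(config, rng, return_molecules)
            if config.dye.mode == "PG_dsDNA":
                pr, se = np.zeros_like(pr), pr
        elif mode == "polymerase":
            pr, se, mo = _simulate_polymerase(config, rng, return_molecules)
        else:  # pragma: no cover
            raise ConfigurationError(f"unhandled mode {mode}")
        prim[r], sec[r] = pr, se
        if return_molecules:
            mols.append(mo)
    return Trajectory(times, prim, sec, sub, mode, mols)


def _qi_reassign(sub: SubstrateSpec, pr, se):
    """Under the RNA dye, duplex RNA species stay primary; ssDNA is weak."""
    if sub.nucleic_kind in ("dsRNA", "RNA_DNA_hybrid", "ssRNA"):
        return pr, np.zeros_like(se)
    return np.zeros_like(pr), pr + se


def _mode_of(config: SimConfig) -> str:
    enz = config.enzyme
    if enz is None or config.enzyme_conc <= 0:
        if config.nickase is None or config.nickase_conc <= 0:
            return "flat"
        return "resection"  # nickase alone: nicks form but no resection
    d = enz.directionality
    if d in ("3to5", "5to3"):
        return "resection"
    if d in ("nonspecific", "rna_hybrid"):
        # a hybrid-specific enzyme on a non-hybrid substrate does nothing
        if d == "rna_hybrid" and config.substrate.nucleic_kind != "RNA_DNA_hybrid":
            return "flat"
        return "distributive"
    if d in ("ss_only", "rna_ss"):
        want = "ssDNA" if d == "ss_only" else "ssRNA"
        return "ss" if config.substrate.nucleic_kind == want else "flat"
    if d == "polymerase":
        return "polymerase" if config.substrate.is_primer_template else "flat"
    if d == "nickase":
        return "resection"
    raise ConfigurationError(f"unknown directionality {d}")


def render_fluorescence(
    trajectory: Trajectory,
    dye: DyeModel,
    substrate_conc: float,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Convert length trajectories to fluorescence:

    F(t) = [alpha·conc·(primary + ss_fraction·secondary)·sat + background]
           × exp(−bleach_rate·t) + N(0, σ²)

    where ``sat`` soft-clips the signal once the equivalent nucleic-acid
    mass exceeds ``saturation_mass``.  With ``noise_sd=None``, σ is
    ``DEFAULT_NOISE_CV`` × the clean t=0 signal of the well.
    """
    if rng is None:
        rng = np.random.default_rng()
    t = trajectory.time_s
    prim, sec = trajectory.primary_nt, trajectory.secondary_nt
    mass = substrate_conc * (prim * DA_PER_BP_DS + sec * DA_PER_NT_SS) * 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mass > 0, dye.saturate(mass) / np.where(mass > 0, mass, 1.0), 1.0)
    signal = dye.alpha_ds * substrate_conc * (prim + dye.ss_fraction * sec) * scale
    clean = (signal + dye.background) * np.exp(-dye.bleach_rate * t)[None, :]
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_CV * (signal[:, :1] + dye.background)
    if np.any(np.asarray(noise_sd) > 0):
        clean = clean + rng.normal(0.0, 1.0, size=clean.shape) * noise_sd
    return clean


# ---------------------------------------------------------------------------
# plate assembly


def make_ladder(
    style: str = "resection",
    full_length: int = 80,
    lengths: tuple = (80, 60, 40, 20),
    conc_nM: float = 50.0,
    n_replicates: int = 3,
) -> LadderSpec:
    """Packaged standard ladders.

    ``resection`` — partial-resection mimics (an L-bp duplex with the
    complementary (full_length−L)-nt ss tail) plus the ss full-length
    oligomer as the 0-bp end product; the paper's conversion end-point for
    resection nucleases.
    ``duplex`` — plain L-bp duplexes plus the ss full-length 0-bp point.
    ``dnase`` — plain duplexes plus a blank (no-substrate) 0-point, the
    appropriate end state for a nonspecific nuclease.
    ``ss`` / ``rna`` / ``hybrid`` — ssDNA / ssRNA / RNA:DNA ladders with a
    blank 0-point, for the reduced-signal and RNA-dye assays.
    """
    members = []
    blank = SubstrateSpec(name="blank", duplex_length=0)
    if style == "resection":
        for L in lengths:
            members.append(
                (
                    SubstrateSpec(
                        name=f"std_{L}bp",
                        duplex_length=L,
                        top_5p_overhang=full_length - L,
                    ),
                    float(L),
                )
            )
        members.append(
            (SubstrateSpec(name=f"std_ss{full_length}", nucleic_kind="ssDNA", ss_length=full_length), 0.0)
        )
    elif style == "duplex":
        for L in lengths:
            members.append((SubstrateSpec(name=f"std_{L}bp", duplex_length=L), float(L)))
        members.append(
            (SubstrateSpec(name=f"std_ss{full_length}", nucleic_kind="ssDNA", ss_length=full_length), 0.0)
        )
    elif style == "dnase":
        for L in lengths:
            members.append((SubstrateSpec(name=f"std_{L}bp", duplex_length=L), float(L)))
        members.append((blank, 0.0))
    elif style == "ss":
        for L in lengths:
            members.append(
                (SubstrateSpec(name=f"std_ss{L}", nucleic_kind="ssDNA", ss_length=L), float(L))
            )
        members.append((blank, 0.0))
    elif style == "rna":
        for L in lengths:
            members.append(
                (SubstrateSpec(name=f"std_rna{L}", nucleic_kind="ssRNA", ss_length=L), float(L))
            )
        members.append((blank, 0.0))
    elif style == "hybrid":
        for L in lengths:
            members.append(
                (
                    SubstrateSpec(name=f"std_hyb{L}", nucleic_kind="RNA_DNA_hybrid", duplex_length=L),
                    float(L),
                )
            )
        members.append((blank, 0.0))
    else:
        raise ConfigurationError(f"unknown ladder style {style!r}")
    return LadderSpec(members=members, conc_nM=conc_nM, n_replicates=n_replicates)


def _well_ids(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    ids = []
    r = 0
    while len(ids) < n:
        for c in range(1, 13):
            ids.append(f"{rows[r % len(rows)]}{c}")
            if len(ids) == n:
                break
        r += 1
    return ids


def simulate_plate(
    sample_configs: list[SimConfig],
    ladder: LadderSpec,
    seed: int | None = None,
    include_controls: bool = True,
) -> PlateRun:
    """Assemble and simulate a full plate: ladder + controls + samples.

    Every sample condition gets matched no-enzyme control wells on the same
    substrate (shared across concentrations of the same substrate), paired
    replicate-to-replicate.  Identical seed ⇒ identical matrix.
    """
    if not sample_configs:
        if ladder is None:
            raise ConfigurationError("empty plate: no samples and no ladder")
    ref = sample_configs[0] if sample_configs else None
    for c in sample_configs[1:]:
        if not np.allclose(c.times, ref.times):
            raise ConfigurationError("all sample configs must share one time base")
        if c.dye != ref.dye:
            raise ConfigurationError("all sample configs must share one dye model")

    missing = []
    if ladder is None:
        missing.append("standard ladder")
    else:
        lens = {v for _, v in ladder.members}
        if len([v for v in lens if v > 0]) < 3:
            missing.append("standard ladder with >= 3 nonzero lengths")
        if 0.0 not in lens:
            missing.append("ladder 0-length end-point well")
    if include_controls is False and any(c.enzyme is not None for c in sample_configs):
        missing.append("matched no-enzyme controls")
    if missing:
        raise ConfigurationError("plate specification missing roles: " + "; ".join(missing))

    # build the well plan
    plan = []  # (config, role, substrate_name, length_bp, replicate, group)
    base = ref if ref is not None else SimConfig(substrate=ladder.members[0][0])
    for subst, length in ladder.members:
        lcfg = replace(
            base,
            substrate=subst,
            enzyme=None,
            enzyme_conc=0.0,
            nickase=None,
            nickase_conc=0.0,
            substrate_conc=ladder.conc_nM,
            n_replicates=1,
            label=f"standard:{subst.name}",
        )
        for rep in range(ladder.n_replicates):
            plan.append((lcfg, "standard", subst.name, length, rep, f"standard:{subst.name}"))

    control_wells: dict[tuple[str, int], str] = {}
    seen_ctrl = set()
    for cfg in sample_configs:
        sname = cfg.substrate.name
        if sname in seen_ctrl:
            continue
        seen_ctrl.add(sname)
        ccfg = replace(cfg, enzyme=None, enzyme_conc=0.0, nickase=None, nickase_conc=0.0, n_replicates=1, label=f"control:{sname}")
        for rep in range(cfg.n_replicates):
            plan.append((ccfg, "control", sname, np.nan, rep, f"control:{sname}"))

    for cfg in sample_configs:
        enz_name = cfg.enzyme.name if cfg.enzyme is not None else (
            cfg.nickase.name if cfg.nickase is not None else "none"
        )
        group = cfg.label or f"{enz_name}:{cfg.enzyme_conc:g}nM:{cfg.substrate.name}"
        for rep in range(cfg.n_replicates):
            plan.append((cfg, "sample", cfg.substrate.name, np.nan, rep, group))

    wells = _well_ids(len(plan))
    times = base.times
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(plan))

    data = {}
    rows = []
    substrates = {}
    for (cfg, role, sname, length, rep, group), well, child in zip(plan, wells, children):
        rng = np.random.default_rng(child)
        one = replace(cfg, n_replicates=1)
        traj = simulate_progress(one, rng=rng)
        F = render_fluorescence(traj, cfg.dye, one.substrate_conc, rng=rng, noise_sd=cfg.noise_sd)
        data[well] = F[0]
        substrates[sname] = one.substrate
        if role == "control":
            control_wells[(sname, rep)] = well
        rows.append(
            {
                "well": well,
                "role": role,
                "substrate": sname,
                "enzyme": cfg.enzyme.name if (role == "sample" and cfg.enzyme is not None) else (
                    cfg.nickase.name if (role == "sample" and cfg.nickase is not None) else ""
                ),
                "enzyme_conc_nM": cfg.enzyme_conc if role == "sample" else 0.0,
                "substrate_conc_nM": one.substrate_conc,
                "replicate_group": group,
                "replicate": rep,
                "length_bp": length,
            }
        )

    wellmap = pd.DataFrame(rows)
    wellmap["control_well"] = [
        control_wells.get((r.substrate, r.replicate), "") if r.role == "sample" else ""
        for r in wellmap.itertuples()
    ]
    df = pd.DataFrame(data, index=pd.Index(times, name="time_s"))
    return PlateRun(data=df, wellmap=wellmap, substrates=substrates)
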