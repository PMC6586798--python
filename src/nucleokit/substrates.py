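"""Substrate library and enzyme structural-accessibility rules.

A substrate is a structured oligonucleotide: a duplex core with optional
single-stranded overhangs at each of the four strand termini, biotin-TEG +
streptavidin end blocks, internal nicks and gaps, and lesions (mismatches,
methylcytosines).  An enzyme is described by its directionality, intrinsic
catalytic rate, and the structural rules gating where it may initiate.

Coordinate conventions
----------------------
Duplex positions are 0-based, left to right.  The *top* strand runs 5'→3'
left to right, the *bottom* strand 5'→3' right to left.  Hence the left
terminus carries the ``top5`` and ``bot3`` ends and the right terminus the
``top3`` and ``bot5`` ends.  Nick and gap positions are stored, as in the
library files, in nt from the owning strand's 5' end and converted to duplex
coordinates internally.  Overhangs are stored as lengths, not sequence;
sequence is optional annotation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SubstrateError",
    "LesionSite",
    "SubstrateSpec",
    "EnzymeSpec",
    "InitiationSite",
    "accessible_ends",
    "molar_to_mass",
    "mass_to_molar",
    "molecular_weight",
]

END_IDS = ("top5", "top3", "bot5", "bot3")
NUCLEIC_KINDS = ("dsDNA", "ssDNA", "ssRNA", "dsRNA", "RNA_DNA_hybrid")
DIRECTIONALITIES = (
    "3to5",
    "5to3",
    "nonspecific",
    "nickase",
    "polymerase",
    "ss_only",
    "rna_ss",
    "rna_hybrid",
)
LESION_KINDS = ("mismatch_TG", "mismatch_AC", "methyl_C")

#: average molar masses, g/mol
DA_PER_BP_DS = 650.0
DA_PER_NT_SS = 330.0


class SubstrateError(ValueError):
    """Raised for a malformed substrate or enzyme description."""


@dataclass(frozen=True)
class LesionSite:
    """A lesion in the duplex: mismatch or methylcytosine.

    ``rate_multiplier`` is the simulator-side ground truth for how the
    per-nt resection hazard changes over a ``window_nt``-wide window centred
    on the lesion.  ``initiation_delay_s`` is the characteristic initiation
    delay (methylation mode) at the reference enzyme concentration.
    ``strand`` may be "top", "bottom" or "both" (a mismatch is a feature of
    the duplex and slows/accelerates fronts on either strand).
    """

    strand: str
    position: int
    kind: str
    rate_multiplier: float = 1.0
    initiation_delay_s: float = 0.0
    window_nt: int = 1

    def validate(self) -> None:
        if self.strand not in ("top", "bottom", "both"):
            raise SubstrateError(f"lesion strand must be top/bottom/both, got {self.strand!r}")
        if self.kind not in LESION_KINDS:
            raise SubstrateError(f"unknown lesion kind {self.kind!r}")
        if not self.rate_multiplier > 0:
            raise SubstrateError("lesion rate_multiplier must be > 0")
        if self.initiation_delay_s < 0:
            raise SubstrateError("lesion initiation_delay_s must be >= 0")
        if self.window_nt < 1:
            raise SubstrateError("lesion window_nt must be >= 1")
        if self.position < 0:
            raise SubstrateError("lesion position must be >= 0")


@dataclass(frozen=True)
class SubstrateSpec:
    """Structural description of one substrate-library member.

    ``duplex_length`` is the paired region in bp.  Pure single-stranded
    substrates (ssDNA/ssRNA) set ``duplex_length = 0`` and carry their
    length in ``ss_length``.  Primer-template substrates set
    ``is_primer_template`` with ``primer_length`` giving the annealed primer
    (duplex) length; ``duplex_length`` is then the full template length.
    """

    name: str
    duplex_length: int = 0
    top_5p_overhang: int = 0
    top_3p_overhang: int = 0
    bottom_5p_overhang: int = 0
    bottom_3p_overhang: int = 0
    blocked_ends: frozenset = frozenset()
    nicks: tuple = ()  # (strand, position nt from that strand's 5')
    gaps: tuple = ()  # (strand, start nt from 5', length nt)
    lesions: tuple = ()  # LesionSite
    motif_sites: tuple = ()  # (strand, position nt from 5', motif str)
    nucleic_kind: str = "dsDNA"
    ss_length: int = 0
    is_primer_template: bool = False
    primer_length: int = 0
    sequence: str | None = None  # optional annotation only

    def __post_init__(self):
        object.__setattr__(self, "blocked_ends", frozenset(self.blocked_ends))
        object.__setattr__(self, "nicks", tuple(tuple(n) for n in self.nicks))
        object.__setattr__(self, "gaps", tuple(tuple(g) for g in self.gaps))
        object.__setattr__(self, "lesions", tuple(self.lesions))
        object.__setattr__(self, "motif_sites", tuple(tuple(m) for m in self.motif_sites))
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.duplex_length < 0 or self.ss_length < 0:
            raise SubstrateError("lengths must be non-negative")
        for v in (
            self.top_5p_overhang,
            self.top_3p_overhang,
            self.bottom_5p_overhang,
            self.bottom_3p_overhang,
        ):
            if v < 0:
                raise SubstrateError("overhang lengths must be non-negative")
        if self.nucleic_kind not in NUCLEIC_KINDS:
            raise SubstrateError(f"unknown nucleic_kind {self.nucleic_kind!r}")
        unknown = self.blocked_ends - set(END_IDS)
        if unknown:
            raise SubstrateError(f"unknown blocked ends: {sorted(unknown)}")
        if self.duplex_length == 0 and self.blocked_ends and not self.ss_length:
            raise SubstrateError("blocked_ends name ends of a zero-length substrate")
        L = self.duplex_length
        gap_spans = {}
        for strand, start, length in self.gaps:
            if strand not in ("top", "bottom"):
                raise SubstrateError(f"gap strand must be top/bottom, got {strand!r}")
            if start < 0 or length <= 0 or start + length > self.strand_length(strand):
                raise SubstrateError(f"gap ({strand},{start},{length}) outside strand")
            gap_spans.setdefault(strand, []).append((start, start + length))
        for strand, pos in self.nicks:
            if strand not in ("top", "bottom"):
                raise SubstrateError(f"nick strand must be top/bottom, got {strand!r}")
            if not 0 < pos < self.strand_length(strand):
                raise SubstrateError(f"nick position {pos} outside strand {strand}")
            for lo, hi in gap_spans.get(strand, ()):
                if lo <= pos <= hi:
                    raise SubstrateError(f"nick at {pos} coincides with gap [{lo},{hi}) on {strand}")
        for les in self.lesions:
            les.validate()
            limit = max(L, self.ss_length)
            if les.position >= max(limit, 1):
                raise SubstrateError(f"lesion position {les.position} outside substrate")
        for strand, pos, motif in self.motif_sites:
            if strand not in ("top", "bottom"):
                raise SubstrateError(f"motif strand must be top/bottom, got {strand!r}")
            if not 0 <= pos < self.strand_length(strand):
                raise SubstrateError(f"motif position {pos} outside strand")
        if self.is_primer_template:
            if not 0 < self.primer_length <= self.duplex_length:
                raise SubstrateError("primer_length must be in (0, duplex_length]")

    # -- geometry helpers ---------------------------------------------
    def strand_length(self, strand: str) -> int:
        """Total nt of one strand (duplex span + its own overhangs)."""
        if self.duplex_length == 0:
            return self.ss_length
        if strand == "top":
            return self.duplex_length + self.top_5p_overhang + self.top_3p_overhang
        return self.duplex_length + self.bottom_5p_overhang + self.bottom_3p_overhang

    @property
    def total_overhang_nt(self) -> int:
        return (
            self.top_5p_overhang
            + self.top_3p_overhang
            + self.bottom_5p_overhang
            + self.bottom_3p_overhang
        )

    def end_overhang(self, end: str) -> int:
        return {
            "top5": self.top_5p_overhang,
            "top3": self.top_3p_overhang,
            "bot5": self.bottom_5p_overhang,
            "bot3": self.bottom_3p_overhang,
        }[end]

    def nick_duplex_coord(self, strand: str, pos: int) -> int:
        """Duplex coordinate of the broken bond (between coord-1 and coord)."""
        if strand == "top":
            return pos - self.top_5p_overhang
        # bottom runs right->left; its 5' end is the right terminus
        return self.duplex_length + self.bottom_5p_overhang - pos

    def lesion_multipliers(self, strand: str) -> "np.ndarray":
        """Per-duplex-position hazard multipliers for fronts on ``strand``."""
        import numpy as np

        n = max(self.duplex_length, self.ss_length)
        mult = np.ones(n)
        for les in self.lesions:
            if les.strand not in (strand, "both"):
                continue
            half = les.window_nt // 2
            lo = max(0, les.position - half)
            hi = min(n, les.position - half + les.window_nt)
            mult[lo:hi] *= les.rate_multiplier
        return mult

    @property
    def methyl_delay_s(self) -> float:
        """Summed characteristic initiation delay over methyl-C lesions."""
        return sum(l.initiation_delay_s for l in self.lesions if l.kind == "methyl_C")

    def with_blocks(self, blocked: frozenset) -> "SubstrateSpec":
        return replace(self, blocked_ends=frozenset(blocked))


@dataclass(frozen=True)
class EnzymeSpec:
    """A nuclease, nickase, or polymerase and its initiation rules.

    ``base_rate`` is the intrinsic catalytic rate per initiated front:
    nt (or bp) per nM enzyme per second for processive modes, or the per-nt
    cleavage hazard (s^-1 nM^-1) for distributive modes (``nonspecific``,
    ``rna_hybrid``).  ``max_permissive_overhang`` gates initiation at ends
    whose attacking strand carries an overhang (None = unlimited);
    ``overhang_rate_attenuation`` maps overhang length to a (0, 1]
    multiplier.  ``motif`` maps a nicking motif to its per-site nicking rate
    (s^-1 nM^-1) for nickases.  ``site_multipliers`` scales initiation from
    internal sites ("nick", "gap").
    """

    name: str
    directionality: str
    base_rate: float
    max_permissive_overhang: int | None = None
    overhang_rate_attenuation: dict = field(default_factory=dict)
    initiates_at: frozenset = frozenset({"blunt_end", "overhang_end"})
    motif: dict = field(default_factory=dict)
    site_multipliers: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "initiates_at", frozenset(self.initiates_at))
        self.validate()

    def validate(self) -> None:
        if self.directionality not in DIRECTIONALITIES:
            raise SubstrateError(f"unknown directionality {self.directionality!r}")
        if not self.base_rate > 0:
            raise SubstrateError("base_rate must be > 0")
        for k, v in self.overhang_rate_attenuation.items():
            if not 0 < v <= 1:
                raise SubstrateError(f"attenuation multiplier for overhang {k} must be in (0,1]")
        for k, v in self.site_multipliers.items():
            if v < 0:
                raise SubstrateError("site multipliers must be >= 0")
        if self.max_permissive_overhang is not None and self.max_permissive_overhang < 0:
            raise SubstrateError("max_permissive_overhang must be >= 0 or None")

    def overhang_multiplier(self, length: int) -> float | None:
        """Initiation multiplier for an end with an ``length``-nt overhang.

        Returns None when the overhang exceeds the permissive maximum
        (no initiation); 1.0 when no attenuation entry exists.
        """
        if length == 0:
            return 1.0
        if self.max_permissive_overhang is not None and length > self.max_permissive_overhang:
            return None
        return float(self.overhang_rate_attenuation.get(length, 1.0))


@dataclass(frozen=True)
class InitiationSite:
    """One place an enzyme may initiate, with geometry for the simulator.

    ``entry`` is the duplex coordinate of the first paired nt the front will
    remove; ``direction`` is +1 (rightward) or -1; ``overhang_nt`` is the ss
    prelude the front traverses before reaching the duplex; ``multiplier``
    scales the per-nt hazard for the whole front.
    """

    kind: str  # end | nick | gap | ss_terminus | primer | internal | motif
    site_id: str
    strand: str  # strand being resected (or extended)
    entry: int
    direction: int
    multiplier: float = 1.0
    overhang_nt: int = 0
    motif: str | None = None


# directionality -> (ends attacked, resected strand per end)
_END_RULES = {
    "3to5": (("top3", "bot3"), {"top3": ("top", None), "bot3": ("bottom", None)}),
    "5to3": (("top5", "bot5"), {"top5": ("top", None), "bot5": ("bottom", None)}),
}
# entry coordinate and direction per end, as fn of duplex length L
_END_GEOMETRY = {
    "top3": lambda L: (L - 1, -1),
    "bot3": lambda L: (0, +1),
    "top5": lambda L: (0, +1),
    "bot5": lambda L: (L - 1, -1),
}


def accessible_ends(
    substrate: SubstrateSpec,
    enzyme: EnzymeSpec,
    blocked_ends: frozenset | None = None,
) -> list[InitiationSite]:
    """Every site ``enzyme`` may initiate from on ``substrate``.

    Blocked ends are excluded; ends whose attacking-strand overhang exceeds
    ``max_permissive_overhang`` are excluded; attenuation multipliers are
    attached.  For nickases, the motif sites are returned; for polymerases,
    the primer 3' terminus.  An enzyme/substrate structural mismatch (e.g. a
    ss-only enzyme on a blunt duplex) yields an empty list, which downstream
    is the negative-control phenotype, not an error.

    ``blocked_ends`` overrides the substrate's own set (used by the
    simulator to enumerate synthesis-purity cases).
    """
    blocked = substrate.blocked_ends if blocked_ends is None else frozenset(blocked_ends)
    d = enzyme.directionality
    sites: list[InitiationSite] = []
    L = substrate.duplex_length

    if d in ("ss_only", "rna_ss"):
        want = "ssDNA" if d == "ss_only" else "ssRNA"
        if substrate.nucleic_kind == want and substrate.ss_length > 0:
            # single front from the strand's attacked terminus
            sites.append(
                InitiationSite(
                    kind="ss_terminus",
                    site_id="ss_terminus",
                    strand="top",
                    entry=substrate.ss_length - 1,
                    direction=-1,
                )
            )
        return sites

    if d == "rna_hybrid":
        if substrate.nucleic_kind == "RNA_DNA_hybrid" and L > 0:
            sites.append(
                InitiationSite(kind="internal", site_id="rna_strand", strand="top", entry=0, direction=+1)
            )
        return sites

    if d == "nonspecific":
        if L > 0 or substrate.ss_length > 0:
            sites.append(
                InitiationSite(kind="internal", site_id="whole", strand="top", entry=0, direction=+1)
            )
        return sites

    if d == "polymerase":
        if substrate.is_primer_template:
            sites.append(
                InitiationSite(
                    kind="primer",
                    site_id="primer_3p",
                    strand="top",
                    entry=substrate.primer_length,
                    direction=+1,
                )
            )
        return sites

    if d == "nickase":
        for strand, pos, motif in substrate.motif_sites:
            if motif in enzyme.motif:
                coord = substrate.nick_duplex_coord(strand, pos)
                sites.append(
                    InitiationSite(
                        kind="motif",
                        site_id=f"motif_{strand}_{pos}_{motif}",
                        strand=strand,
                        entry=coord,
                        direction=0,
                        multiplier=float(enzyme.motif[motif]),
                        motif=motif,
                    )
                )
        return sites

    if d not in _END_RULES:
        return sites
    if L == 0 or substrate.nucleic_kind not in ("dsDNA", "dsRNA", "RNA_DNA_hybrid"):
        return sites

    ends, strand_of = _END_RULES[d]
    for end in ends:
        if end in blocked:
            continue
        ov = substrate.end_overhang(end)
        if ov == 0 and "blunt_end" not in enzyme.initiates_at:
            continue
        if ov > 0 and "overhang_end" not in enzyme.initiates_at:
            continue
        mult = enzyme.overhang_multiplier(ov)
        if mult is None:
            continue
        entry, direction = _END_GEOMETRY[end](L)
        sites.append(
            InitiationSite(
                kind="end",
                site_id=end,
                strand=strand_of[end][0],
                entry=entry,
                direction=direction,
                multiplier=mult,
                overhang_nt=ov,
            )
        )

    m_nick = float(enzyme.site_multipliers.get("nick", 1.0))
    m_gap = float(enzyme.site_multipliers.get("gap", 1.0))
    if "nick" in enzyme.initiates_at:
        for strand, pos in substrate.nicks:
            coord = substrate.nick_duplex_coord(strand, pos)
            entry, direction = _internal_entry(d, strand, coord)
            if 0 <= entry < L:
                sites.append(
                    InitiationSite(
                        kind="nick",
                        site_id=f"nick_{strand}_{pos}",
                        strand=strand,
                        entry=entry,
                        direction=direction,
                        multiplier=m_nick,
                    )
                )
    if "gap" in enzyme.initiates_at:
        for strand, start, length in substrate.gaps:
            lo = substrate.nick_duplex_coord(strand, start + length) if strand == "bottom" else substrate.nick_duplex_coord(strand, start)
            hi = lo + length
            # front resects away from the gap in the enzyme's direction
            entry, direction = _gap_entry(d, strand, lo, hi)
            if 0 <= entry < L:
                sites.append(
                    InitiationSite(
                        kind="gap",
                        site_id=f"gap_{strand}_{start}",
                        strand=strand,
                        entry=entry,
                        direction=direction,
                        multiplier=m_gap,
                    )
                )
    return sites


def _internal_entry(direction: str, strand: str, coord: int) -> tuple[int, int]:
    """Entry coordinate and travel direction for a front starting at a nick.

    A nick between duplex coords ``coord-1`` and ``coord`` exposes a new 3'
    and a new 5' terminus; which fragment is attacked depends on enzyme
    directionality and strand polarity.
    """
    if direction == "3to5":
        return (coord - 1, -1) if strand == "top" else (coord, +1)
    # 5to3
    return (coord, +1) if strand == "top" else (coord - 1, -1)


def _gap_entry(direction: str, strand: str, lo: int, hi: int) -> tuple[int, int]:
    """Entry for a front initiating at a gap spanning duplex [lo, hi)."""
    if direction == "3to5":
        return (lo - 1, -1) if strand == "top" else (hi, +1)
    return (hi, +1) if strand == "top" else (lo - 1, -1)


# ---------------------------------------------------------------------------
# molar <-> mass conversion


def molecular_weight(substrate: SubstrateSpec, da_per_bp: float = DA_PER_BP_DS, da_per_nt: float = DA_PER_NT_SS) -> float:
    """Approximate molecular weight (g/mol) of one substrate molecule."""
    ss_nt = substrate.total_overhang_nt + substrate.ss_length
    if substrate.is_primer_template:
        # template beyond the primer is single-stranded
        ss_nt += substrate.duplex_length - substrate.primer_length
        return substrate.primer_length * da_per_bp + ss_nt * da_per_nt
    return substrate.duplex_length * da_per_bp + ss_nt * da_per_nt


def molar_to_mass(substrate: SubstrateSpec, molar_nM: float, **kw) -> float:
    """nM -> ng/µL:  mass = molar × MW × 1e-6 (50 nM 80-bp dsDNA → 2.6)."""
    if molar_nM < 0:
        raise SubstrateError("molar concentration must be >= 0")
    return molar_nM * molecular_weight(substrate, **kw) * 1e-6


def mass_to_molar(substrate: SubstrateSpec, mass_ng_per_uL: float, **kw) -> float:
    """ng/µL -> nM, inverse of :func:`molar_to_mass`."""
    if mass_ng_per_uL < 0:
        raise SubstrateError("mass concentration must be >= 0")
    mw = molecular_weight(substrate, **kw)
    if mw == 0:
        raise SubstrateError("substrate has zero molecular weight")
    return mass_ng_per_uL / (mw * 1e-6)
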