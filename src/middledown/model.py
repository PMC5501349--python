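"""Core data model for middle-down histone-tail proteoforms.

Middle-down MS analyses long (~50 aa) polypeptides — here GluC-cleaved
histone N-terminal tails — so that combinatorial patterns of methylation
and acetylation stay connected on one molecule.  This module holds the
identity layer of the pipeline:

* :class:`TailSequence` — the polypeptide under study (default: human
  histone H3 residues 1–50).
* :class:`Modification` — one site-resolved mark: me1/me2/me3/ac, with a
  count of heavy (13CD3) methyl groups deposited from heavy methionine
  via SAM.
* :class:`LabelScheme` — the metabolic-labeling mass shifts: SILAC-style
  heavy K(13C6,15N2)/R(13C6,15N4) on the sequence channel and the
  +4.0222 Da heavy-methyl shift on the PTM channel.
* :class:`Proteoform` — a tail + a set of mods + a label channel; the unit
  everything downstream identifies and quantifies.
* monoisotopic masses, m/z, and ETD c/z• fragment ladders.

Notation: marks are written ``K27me2:2`` — residue, parent-protein site,
kind, and (after the colon) the number of heavy methyl groups.  The colon
suffix is omitted when all methyls are light.  Concatenated site-ascending
tokens name a proteoform, e.g. ``K14acK27me2:2``; the empty string is the
unmodified tail.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from pyteomics import mass as _pmass

# --- monoisotopic constants (Da), from the NIST isotope table ------------
WATER = _pmass.calculate_mass(formula="H2O")
PROTON = 1.007276466622
HYDROGEN = _pmass.nist_mass["H"][1][0]
CH2 = _pmass.calculate_mass(formula="CH2")          # one methylation unit
ACETYL = _pmass.calculate_mass(formula="C2H2O")      # acetylation delta
C_ION_OFFSET = _pmass.calculate_mass(formula="NH3")  # c ion = prefix + NH3
Z_ION_OFFSET = WATER + HYDROGEN - C_ION_OFFSET       # z• ion = suffix + 1.991841

_D13C = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]
_D2H = _pmass.nist_mass["H"][2][0] - _pmass.nist_mass["H"][1][0]
_D15N = _pmass.nist_mass["N"][15][0] - _pmass.nist_mass["N"][14][0]

#: K(13C6, 15N2) minus light lysine
HEAVY_K_DELTA = 6 * _D13C + 2 * _D15N
#: R(13C6, 15N4) minus light arginine
HEAVY_R_DELTA = 6 * _D13C + 4 * _D15N
#: one 13CD3 methyl minus one CH3 methyl (~4.0222 Da)
HEAVY_METHYL_DELTA = _D13C + 3 * _D2H

RESIDUE_MASS = dict(_pmass.std_aa_mass)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: methyl count per modification kind (acetyl carries no methyl)
MOD_KINDS = {"me1": 1, "me2": 2, "me3": 3, "ac": 0}

#: default residue rules: mono/dimethyl on K and R, trimethyl and acetyl on K only
DEFAULT_MOD_RULES: dict[str, tuple[str, ...]] = {
    "K": ("me1", "me2", "me3", "ac"),
    "R": ("me1", "me2"),
}

LIGHT = "light"
HEAVY_KR = "heavy_KR"
CHANNELS = (LIGHT, HEAVY_KR)


class NotationError(ValueError):
    """Raised for malformed or tail-inconsistent proteoform notation."""


@dataclass(frozen=True)
class TailSequence:
    """A middle-down polypeptide in parent-protein coordinates.

    ``first_position`` is the 1-based position of the first residue in the
    parent protein, so mark names (K4, K9, …) keep the field's standard
    histone numbering regardless of where the tail starts.
    """

    name: str
    residues: str
    first_position: int = 1
    cleavage_context: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("tail sequence must be non-empty")
        bad = set(self.residues) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residue letters: {sorted(bad)}")
        if self.first_position < 1:
            raise ValueError("first_position must be >= 1")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def last_position(self) -> int:
        return self.first_position + len(self.residues) - 1

    def residue_at(self, site: int) -> str:
        """Residue letter at a parent-protein position."""
        if not self.first_position <= site <= self.last_position:
            raise ValueError(
                f"site {site} outside tail {self.name} "
                f"({self.first_position}..{self.last_position})"
            )
        return self.residues[site - self.first_position]

    def sites_of(self, letters: str) -> tuple[int, ...]:
        """Parent-protein positions of the given residue letters, in order."""
        return tuple(
            self.first_position + i
            for i, aa in enumerate(self.residues)
            if aa in letters
        )


#: human histone H3 residues 1-50, released by GluC cleavage after E50
H3_TAIL = TailSequence(
    name="H3_1_50",
    residues="ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALRE",
    first_position=1,
    cleavage_context="GluC after E50, 0 missed cleavages",
)

#: the nine H3 sites followed throughout the analyses
H3_MODIFIABLE_SITES = (4, 8, 9, 14, 18, 23, 26, 27, 36)


@dataclass(frozen=True, order=True)
class Modification:
    """One mark at one site: kind me1/me2/me3/ac with ``heavy_methyls`` of
    its methyl groups carrying the 13CD3 label (written after the colon,
    e.g. me2:1).  Acetyl has no methyls, so heavy_methyls must be 0."""

    site: int
    residue: str
    kind: str
    heavy_methyls: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MOD_KINDS:
            raise ValueError(f"unknown modification kind {self.kind!r}")
        k = MOD_KINDS[self.kind]
        if not 0 <= self.heavy_methyls <= k:
            raise ValueError(
                f"{self.residue}{self.site}{self.kind}: heavy methyl count "
                f"{self.heavy_methyls} outside 0..{k}"
            )

    @property
    def methyl_count(self) -> int:
        return MOD_KINDS[self.kind]

    @property
    def is_hybrid(self) -> bool:
        """True when partially heavy (0 < h < k): part of the methylation
        state predates labeling and part was deposited after."""
        return 0 < self.heavy_methyls < self.methyl_count

    @property
    def token(self) -> str:
        s = f"{self.residue}{self.site}{self.kind}"
        if self.heavy_methyls:
            s += f":{self.heavy_methyls}"
        return s


@dataclass(frozen=True)
class LabelScheme:
    """Metabolic-labeling mass shifts and which channels are active.

    ``allow_methionine_tails`` guards a subtlety of heavy-methyl labeling:
    growth in methionine-(methyl-13CD3) also shifts methionine residues in
    the sequence itself, which this model does not account for.  H3 1-50
    contains no M; tails that do are rejected unless the override is set.
    """

    heavy_K_delta: float = HEAVY_K_DELTA
    heavy_R_delta: float = HEAVY_R_DELTA
    heavy_methyl_delta: float = HEAVY_METHYL_DELTA
    sequence_channel_enabled: bool = True
    methyl_channel_enabled: bool = True
    allow_methionine_tails: bool = False

    def __post_init__(self) -> None:
        for name in ("heavy_K_delta", "heavy_R_delta", "heavy_methyl_delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def check_tail(self, tail: TailSequence) -> None:
        if (
            self.methyl_channel_enabled
            and "M" in tail.residues
            and not self.allow_methionine_tails
        ):
            raise ValueError(
                f"tail {tail.name} contains methionine; its sequence would "
                "itself be heavy under methyl labeling "
                "(set allow_methionine_tails=True to override)"
            )


DEFAULT_SCHEME = LabelScheme()


@dataclass(frozen=True)
class Proteoform:
    """A tail with a canonically ordered set of mods and a label channel.

    ``heavy_residues`` optionally restricts the heavy-KR label to a subset
    of K/R positions (partial sequence labeling); by default channel
    ``heavy_KR`` means every K and R is heavy.
    """

    tail: TailSequence
    mods: tuple[Modification, ...] = ()
    channel: str = LIGHT
    heavy_residues: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        ordered = tuple(sorted(self.mods, key=lambda m: m.site))
        object.__setattr__(self, "mods", ordered)
        seen: set[int] = set()
        for m in ordered:
            if m.site in seen:
                raise ValueError(f"more than one modification at site {m.site}")
            seen.add(m.site)
            actual = self.tail.residue_at(m.site)
            if actual != m.residue:
                raise ValueError(
                    f"modification {m.token}: tail has {actual} at site {m.site}"
                )
        if self.heavy_residues is not None:
            kr = set(self.tail.sites_of("KR"))
            extra = set(self.heavy_residues) - kr
            if extra:
                raise ValueError(f"heavy_residues not K/R sites: {sorted(extra)}")

    @property
    def notation(self) -> str:
        return format_notation(self.mods)

    @property
    def n_heavy_methyls(self) -> int:
        return sum(m.heavy_methyls for m in self.mods)

    def mod_at(self, site: int) -> Modification | None:
        for m in self.mods:
            if m.site == site:
                return m
        return None

    def with_mod(self, mod: Modification) -> "Proteoform":
        return Proteoform(
            tail=self.tail,
            mods=self.mods + (mod,),
            channel=self.channel,
            heavy_residues=self.heavy_residues,
        )

    def key(self) -> tuple[str, str, str]:
        return (self.tail.name, self.notation, self.channel)


@dataclass(frozen=True)
class FragmentIon:
    """One ETD fragment: series 'c' (N-terminal) or 'z' (C-terminal z•),
    1-based index, neutral monoisotopic mass."""

    series: str
    index: int
    neutral_mass: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}"


@dataclass
class Spectrum:
    """A deconvoluted MS/MS spectrum: neutral precursor mass, charge, and
    (neutral fragment mass, intensity) peaks sorted by mass."""

    id: str
    precursor_neutral_mass: float
    precursor_charge: int = 8
    peaks: list[tuple[float, float]] = field(default_factory=list)
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be >= 0")

    @property
    def total_intensity(self) -> float:
        return float(sum(i for _, i in self.peaks))


# --- masses ---------------------------------------------------------------

def mod_delta(mod: Modification, scheme: LabelScheme = DEFAULT_SCHEME) -> float:
    """Mass added by one modification: k·CH2 + h·Δme for a k-fold methyl
    with h heavy methyls; C2H2O for acetyl."""
    if mod.kind == "ac":
        return ACETYL
    return mod.methyl_count * CH2 + mod.heavy_methyls * scheme.heavy_methyl_delta


def _residue_masses(p: Proteoform, scheme: LabelScheme) -> list[float]:
    """Per-residue masses including site mods and sequence labels."""
    scheme.check_tail(p.tail)
    tail = p.tail
    out: list[float] = []
    heavy_sites: set[int]
    if p.channel == HEAVY_KR:
        heavy_sites = (
            set(p.heavy_residues)
            if p.heavy_residues is not None
            else set(tail.sites_of("KR"))
        )
    else:
        heavy_sites = set()
    mods_by_site = {m.site: m for m in p.mods}
    for i, aa in enumerate(tail.residues):
        site = tail.first_position + i
        try:
            m = RESIDUE_MASS[aa]
        except KeyError:  # pragma: no cover - TailSequence already validates
            raise ValueError(f"unknown residue {aa!r} at position {site}") from None
        if site in heavy_sites:
            m += scheme.heavy_K_delta if aa == "K" else scheme.heavy_R_delta
        if site in mods_by_site:
            m += mod_delta(mods_by_site[site], scheme)
        out.append(m)
    return out


def proteoform_mass(p: Proteoform, scheme: LabelScheme = DEFAULT_SCHEME) -> float:
    """Neutral monoisotopic mass: residues + water + mods + labels."""
    return sum(_residue_masses(p, scheme)) + WATER


def mz(neutral_mass: float, z: int) -> float:
    """m/z of a neutral mass at charge z (protonation)."""
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + z * PROTON) / z


def neutral_mass_from_mz(mz_value: float, z: int) -> float:
    if z < 1:
        raise ValueError("charge must be >= 1")
    return mz_value * z - z * PROTON


def ion_ladder(
    p: Proteoform, scheme: LabelScheme = DEFAULT_SCHEME
) -> list[FragmentIon]:
    """Full ETD ladder c1..c(n-1) and z•1..z•(n-1).

    c_i = (sum of the first i residue masses, mods and labels included)
    + NH3; z•_j = (sum of the last j) + 1.991841.  For every split,
    c_i + z•_(n-i) = M + 1.007825 (one hydrogen), independent of mods.
    """
    masses = _residue_masses(p, scheme)
    n = len(masses)
    if n < 2:
        raise ValueError("need at least 2 residues to fragment")
    ions: list[FragmentIon] = []
    acc = 0.0
    for i in range(n - 1):
        acc += masses[i]
        ions.append(FragmentIon("c", i + 1, acc + C_ION_OFFSET))
    acc = 0.0
    for j in range(n - 1):
        acc += masses[n - 1 - j]
        ions.append(FragmentIon("z", j + 1, acc + Z_ION_OFFSET))
    return ions


# --- notation -------------------------------------------------------------

_TOKEN_RE = re.compile(r"([A-Z])(\d+)(me[123]|ac)(?::(\d+))?")


def iter_tokens(s: str) -> Iterator[tuple[str, int, str, int]]:
    """Yield (residue, site, kind, heavy) tuples from compact notation.

    Raises :class:`NotationError` on any malformed stretch, naming it.
    """
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise NotationError(f"malformed notation near {s[pos:pos + 12]!r}")
        residue, site, kind, heavy = m.groups()
        yield residue, int(site), kind, int(heavy) if heavy else 0
        pos = m.end()


def parse_notation(s: str, tail: TailSequence) -> tuple[Modification, ...]:
    """Parse compact notation (e.g. ``"K14acK27me2:2"``) against a tail.

    Inverse of :func:`format_notation`.  The empty string is the
    unmodified tail.  Errors name the offending token: unknown site,
    residue mismatch, invalid kind/degree, or heavy count above the
    methyl count.
    """
    mods: list[Modification] = []
    for residue, site, kind, heavy in iter_tokens(s.strip()):
        token = f"{residue}{site}{kind}" + (f":{heavy}" if heavy else "")
        if not tail.first_position <= site <= tail.last_position:
            raise NotationError(f"{token}: site outside tail {tail.name}")
        actual = tail.residue_at(site)
        if actual != residue:
            raise NotationError(f"{token}: tail has {actual} at site {site}")
        try:
            mods.append(Modification(site, residue, kind, heavy))
        except ValueError as exc:
            raise NotationError(f"{token}: {exc}") from None
    out = tuple(sorted(mods, key=lambda m: m.site))
    sites = [m.site for m in out]
    if len(set(sites)) != len(sites):
        raise NotationError(f"duplicate site in {s!r}")
    return out


def format_notation(mods: Sequence[Modification]) -> str:
    """Canonical site-ascending concatenation; ``:h`` omitted when h=0."""
    return "".join(m.token for m in sorted(mods, key=lambda m: m.site))


def make_proteoform(
    tail: TailSequence, notation: str = "", channel: str = LIGHT
) -> Proteoform:
    """Build a proteoform from compact notation."""
    return Proteoform(tail=tail, mods=parse_notation(notation, tail), channel=channel)
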