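"""Spectrum-to-proteoform search and site-localization filtering.

The search matches a deconvoluted ETD spectrum against every proteoform of
the tail whose mass fits the precursor window (default 2.1 Da, wide enough
to absorb deconvolution and isotope-pick errors).  Candidates are built
composition-first: solve for total methyl units, acetyls and heavy methyls
that fit the mass, then place them on the allowed sites.

Accepted identifications must survive the localization filter: every
modification needs at least one matched *site-determining* ion — a
fragment whose theoretical mass differs from every rival placement —
within 30 ppm.  Peptides whose modification sites cannot be pinned down
this way are discarded as ambiguous, which is what keeps near-isobaric
assignments (trimethyl 42.047 Da vs acetyl 42.011 Da) honest.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    ACETYL,
    CH2,
    DEFAULT_MOD_RULES,
    DEFAULT_SCHEME,
    HEAVY_KR,
    LIGHT,
    MOD_KINDS,
    C_ION_OFFSET,
    Z_ION_OFFSET,
    FragmentIon,
    LabelScheme,
    Modification,
    Proteoform,
    Spectrum,
    TailSequence,
    _residue_masses,
    ion_ladder,
    proteoform_mass,
)

#: two theoretical ions closer than this are treated as indistinguishable
MASS_DISTINCT_EPS = 1e-4

ACCEPTED = "accepted"
REJECTED_AMBIGUOUS = "rejected_ambiguous"
REJECTED_SCORE = "rejected_score"


class CandidateCapError(RuntimeError):
    """Raised when candidate enumeration exceeds the configured cap; the
    remedy is tighter modification rules or a smaller precursor window,
    never silent truncation."""


@dataclass(frozen=True)
class SearchConfig:
    """Search and filter parameters.

    Defaults follow standard middle-down practice for GluC histone tails:
    2.1 Da precursor window, 0.01 Da fragment tolerance during search
    (below the 0.0364 Da trimethyl/acetyl gap), 30 ppm for the
    localization filter, and a 0.05 Da window defining which candidates
    count as co-isolated isobars.
    """

    precursor_tol: float = 2.1
    fragment_tol_search: float = 0.01
    fragment_tol_filter_ppm: float = 30.0
    isobaric_window: float = 0.05
    mod_rules: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MOD_RULES)
    )
    modifiable_sites: tuple[int, ...] | None = None
    max_mods: int = 9
    max_candidates: int = 200_000
    scheme: LabelScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        for name in ("precursor_tol", "fragment_tol_search", "fragment_tol_filter_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        both = all(
            any(k in kinds for kinds in self.mod_rules.values())
            for k in ("me3", "ac")
        )
        if both and self.fragment_tol_search >= 3 * CH2 - ACETYL:
            raise ValueError(
                "fragment_tol_search must stay below the me3/ac mass "
                f"difference ({3 * CH2 - ACETYL:.4f} Da) when both are enabled"
            )

    def channels(self) -> tuple[str, ...]:
        return (LIGHT, HEAVY_KR) if self.scheme.sequence_channel_enabled else (LIGHT,)

    def site_states(
        self, tail: TailSequence
    ) -> list[tuple[int, str, tuple[str, ...]]]:
        """(site, residue, allowed kinds) for each modifiable site."""
        if self.modifiable_sites is not None:
            sites = self.modifiable_sites
        else:
            sites = tuple(
                tail.first_position + i
                for i, aa in enumerate(tail.residues)
                if aa in self.mod_rules
            )
        out = []
        for s in sites:
            aa = tail.residue_at(s)
            kinds = self.mod_rules.get(aa, ())
            if kinds:
                out.append((s, aa, tuple(kinds)))
        return out


def enumerate_candidates(
    precursor_mass: float, cfg: SearchConfig, tail: TailSequence
) -> list[Proteoform]:
    """All proteoforms of ``tail`` within the precursor window.

    Composition-first: for each label channel, enumerate totals
    (a methyl units, b acetyls, c heavy methyls) whose summed delta fits
    ``precursor_mass - unmodified_mass`` within ``precursor_tol``, then
    place them on the modifiable sites and distribute the heavy methyls
    over the placed marks.  Deterministic order: fewest mods first, then
    notation, then channel.  Exceeding ``max_candidates`` raises
    :class:`CandidateCapError`.
    """
    if precursor_mass <= 0:
        raise ValueError("precursor mass must be > 0")
    states = cfg.site_states(tail)
    me_caps = [
        max((MOD_KINDS[k] for k in kinds if k != "ac"), default=0)
        for _, _, kinds in states
    ]
    ac_ok = [int("ac" in kinds) for _, _, kinds in states]
    # suffix capacities for pruning the placement DFS
    nsite = len(states)
    suf_me = [0] * (nsite + 1)
    suf_ac = [0] * (nsite + 1)
    for i in range(nsite - 1, -1, -1):
        suf_me[i] = suf_me[i + 1] + me_caps[i]
        suf_ac[i] = suf_ac[i + 1] + ac_ok[i]

    scheme = cfg.scheme
    out: list[Proteoform] = []

    def place(
        i: int, a_left: int, b_left: int, n_mods: int,
        chosen: list[tuple[int, str, str]], channel: str, c_total: int,
    ) -> None:
        if a_left > suf_me[i] or b_left > suf_ac[i]:
            return
        if i == nsite:
            if a_left == 0 and b_left == 0:
                distribute_heavy(chosen, channel, c_total)
            return
        site, aa, kinds = states[i]
        # unmodified at this site
        place(i + 1, a_left, b_left, n_mods, chosen, channel, c_total)
        if n_mods >= cfg.max_mods:
            return
        for kind in kinds:
            k = MOD_KINDS[kind]
            if kind == "ac":
                if b_left > 0:
                    chosen.append((site, aa, kind))
                    place(i + 1, a_left, b_left - 1, n_mods + 1, chosen,
                          channel, c_total)
                    chosen.pop()
            elif k <= a_left:
                chosen.append((site, aa, kind))
                place(i + 1, a_left - k, b_left, n_mods + 1, chosen,
                      channel, c_total)
                chosen.pop()

    def distribute_heavy(
        chosen: list[tuple[int, str, str]], channel: str, c_total: int
    ) -> None:
        me_marks = [t for t in chosen if t[2] != "ac"]
        caps = [MOD_KINDS[t[2]] for t in me_marks]
        suf = [0] * (len(caps) + 1)
        for i in range(len(caps) - 1, -1, -1):
            suf[i] = suf[i + 1] + caps[i]

        def rec(j: int, c_left: int, hs: list[int]) -> None:
            if c_left > suf[j]:
                return
            if j == len(me_marks):
                if c_left == 0:
                    emit(chosen, hs, channel)
                return
            for h in range(0, min(caps[j], c_left) + 1):
                hs.append(h)
                rec(j + 1, c_left - h, hs)
                hs.pop()

        rec(0, c_total, [])

    def emit(chosen: list[tuple[int, str, str]], hs: list[int], channel: str) -> None:
        mods = []
        hi = 0
        for site, aa, kind in chosen:
            if kind == "ac":
                mods.append(Modification(site, aa, "ac"))
            else:
                mods.append(Modification(site, aa, kind, hs[hi]))
                hi += 1
        out.append(Proteoform(tail=tail, mods=tuple(mods), channel=channel))
        if len(out) > cfg.max_candidates:
            raise CandidateCapError(
                f"more than {cfg.max_candidates} candidates in the "
                f"{cfg.precursor_tol} Da window around {precursor_mass:.3f}; "
                "tighten mod_rules, max_mods or the precursor tolerance"
            )

    a_cap = sum(me_caps)
    b_cap = sum(ac_ok)
    for channel in cfg.channels():
        base = proteoform_mass(Proteoform(tail=tail, channel=channel), scheme)
        lo = precursor_mass - cfg.precursor_tol - base
        hi = precursor_mass + cfg.precursor_tol - base
        if hi < -1e-9:
            continue
        c_cap_enabled = scheme.methyl_channel_enabled
        for a in range(a_cap + 1):
            for b in range(b_cap + 1):
                for c in range(0, (a if c_cap_enabled else 0) + 1):
                    delta = a * CH2 + b * ACETYL + c * scheme.heavy_methyl_delta
                    if lo <= delta <= hi:
                        place(0, a, b, 0, [], channel, c)
    out.sort(key=lambda p: (len(p.mods), p.notation, p.channel))
    return out


# --- fragment matching ----------------------------------------------------

@dataclass(frozen=True)
class FragmentMatch:
    ion: FragmentIon
    peak_index: int
    peak_mass: float
    peak_intensity: float

    @property
    def error_da(self) -> float:
        return self.peak_mass - self.ion.neutral_mass

    @property
    def error_ppm(self) -> float:
        return self.error_da / self.ion.neutral_mass * 1e6


def match_fragments(
    spectrum: Spectrum,
    p: Proteoform,
    tol: float = 0.01,
    unit: str = "Da",
    scheme: LabelScheme = DEFAULT_SCHEME,
) -> list[FragmentMatch]:
    """Greedily assign spectrum peaks to the theoretical c/z• ladder.

    For each ion, the most intense unused peak within the tolerance wins
    (ties broken by smaller mass error); each peak is used at most once
    per ion series.  ``unit`` is ``"Da"`` or ``"ppm"``.
    """
    if unit not in ("Da", "ppm"):
        raise ValueError("unit must be 'Da' or 'ppm'")
    masses = [m for m, _ in spectrum.peaks]
    matches: list[FragmentMatch] = []
    used: dict[str, set[int]] = {"c": set(), "z": set()}
    for ion in ion_ladder(p, scheme):
        w = tol if unit == "Da" else ion.neutral_mass * tol * 1e-6
        lo = bisect.bisect_left(masses, ion.neutral_mass - w)
        hi = bisect.bisect_right(masses, ion.neutral_mass + w)
        best = None
        for idx in range(lo, hi):
            if idx in used[ion.series]:
                continue
            pm, pi = spectrum.peaks[idx]
            key = (pi, -abs(pm - ion.neutral_mass))
            if best is None or key > best[0]:
                best = (key, idx, pm, pi)
        if best is not None:
            _, idx, pm, pi = best
            used[ion.series].add(idx)
            matches.append(FragmentMatch(ion, idx, pm, pi))
    return matches


def score_psm(
    matched: list[FragmentMatch],
    p: Proteoform,
    spectrum: Spectrum,
    scheme: LabelScheme = DEFAULT_SCHEME,
) -> float:
    """Intensity-weighted matched fraction in [0, 1].

    Mean of (matched ions / theoretical ions) and (matched intensity /
    total spectrum intensity).  1.0 when every theoretical ion matches and
    carries all the signal; 0.0 when nothing matches.
    """
    n_theor = 2 * (len(p.tail) - 1)
    f_count = len(matched) / n_theor if n_theor else 0.0
    total = spectrum.total_intensity
    f_int = sum(m.peak_intensity for m in matched) / total if total > 0 else 0.0
    return 0.5 * (f_count + f_int)


def _ladder_mass_array(p: Proteoform, scheme: LabelScheme) -> np.ndarray:
    res = np.asarray(_residue_masses(p, scheme))
    c = np.cumsum(res[:-1]) + C_ION_OFFSET
    z = np.cumsum(res[::-1][:-1]) + Z_ION_OFFSET
    return np.concatenate([c, z])


def _quick_score(
    peak_masses: np.ndarray,
    peak_intensities: np.ndarray,
    total_intensity: float,
    ladder: np.ndarray,
    tol: float,
) -> float:
    """Ranking score: same formula as :func:`score_psm` but computed
    vectorized and without the one-peak-per-series bookkeeping (identical
    whenever theoretical ions do not compete for one peak)."""
    if peak_masses.size == 0:
        return 0.0
    idx = np.searchsorted(peak_masses, ladder)
    left = np.clip(idx - 1, 0, peak_masses.size - 1)
    right = np.clip(idx, 0, peak_masses.size - 1)
    dl = np.abs(peak_masses[left] - ladder)
    dr = np.abs(peak_masses[right] - ladder)
    nearest = np.where(dl <= dr, left, right)
    dist = np.minimum(dl, dr)
    hit = dist <= tol
    f_count = hit.sum() / ladder.size
    matched_peaks = np.unique(nearest[hit])
    f_int = (
        peak_intensities[matched_peaks].sum() / total_intensity
        if total_intensity > 0
        else 0.0
    )
    return 0.5 * (f_count + f_int)


# --- site-determining ions and the localization filter --------------------

def site_determining_ions(
    p: Proteoform,
    rivals: list[Proteoform],
    scheme: LabelScheme = DEFAULT_SCHEME,
    how: str = "intersection",
) -> dict[Modification, tuple[FragmentIon, ...]]:
    """Per-modification ions that pin the mark to its site.

    For each mod of ``p``, the rivals that matter are the isobaric
    candidates *not* carrying that same mod; an ion discriminates against
    a rival when its theoretical mass differs from the rival's
    corresponding ion by more than :data:`MASS_DISTINCT_EPS`.

    ``how='intersection'`` (default) returns the ions that differ from
    *every* relevant rival at once — ions whose observed intensity is
    guaranteed to come from ``p`` alone, which is what FIRR splitting
    needs.  ``how='union'`` returns the ions that discriminate against at
    least one rival — the full evidence set the localization filter draws
    on.  With no relevant rival the mod is unambiguous and every ion
    qualifies.
    """
    if how not in ("intersection", "union"):
        raise ValueError("how must be 'intersection' or 'union'")
    own = ion_ladder(p, scheme)
    rival_ladders = []
    for r in rivals:
        if r.key() == p.key():
            continue
        rival_ladders.append(
            (set(r.mods), {(i.series, i.index): i.neutral_mass for i in ion_ladder(r, scheme)})
        )
    out: dict[Modification, tuple[FragmentIon, ...]] = {}
    for mod in p.mods:
        relevant = [lad for rmods, lad in rival_ladders if mod not in rmods]
        if not relevant:
            out[mod] = tuple(own)
            continue
        agg = all if how == "intersection" else any
        sdi = tuple(
            ion
            for ion in own
            if agg(
                abs(ion.neutral_mass - lad[(ion.series, ion.index)])
                > MASS_DISTINCT_EPS
                for lad in relevant
            )
        )
        out[mod] = sdi
    return out


@dataclass
class PSM:
    """A spectrum-to-proteoform match with localization evidence."""

    spectrum_id: str
    proteoform: Proteoform
    matches: list[FragmentMatch]
    score: float
    localization: dict[Modification, tuple[FragmentMatch, ...]] = field(
        default_factory=dict
    )
    status: str = "unfiltered"

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    @property
    def max_ppm_error(self) -> float:
        return max((abs(m.error_ppm) for m in self.matches), default=0.0)

    @property
    def matched_intensity(self) -> float:
        return float(sum(m.peak_intensity for m in self.matches))


def isoscale_filter(
    psm: PSM, rivals: list[Proteoform], cfg: SearchConfig
) -> PSM:
    """Set the PSM's status by the site-localization rule.

    Accepted iff every modification's placement is unambiguous: every
    rival placement of that mod must be excluded by at least one matched
    discriminating ion within ``fragment_tol_filter_ppm`` (an ion whose
    theoretical mass differs between the assignment and that rival).
    Otherwise the PSM is rejected as ambiguous.  Unmodified proteoforms
    accept on score alone (any non-empty match).

    The per-mod ``localization`` evidence recorded on the returned PSM is
    the matched discriminating ions (union over rivals).
    """
    if not psm.matches:
        return replace(psm, status=REJECTED_SCORE, localization={})
    if not psm.proteoform.mods:
        return replace(psm, status=ACCEPTED, localization={})
    p = psm.proteoform
    own = {(i.series, i.index): i.neutral_mass for i in ion_ladder(p, cfg.scheme)}
    rival_ladders = []
    for r in rivals:
        if r.key() == p.key():
            continue
        rival_ladders.append(
            (set(r.mods),
             {(i.series, i.index): i.neutral_mass for i in ion_ladder(r, cfg.scheme)})
        )
    good = [
        m for m in psm.matches
        if abs(m.error_ppm) <= cfg.fragment_tol_filter_ppm
    ]
    localization: dict[Modification, tuple[FragmentMatch, ...]] = {}
    status = ACCEPTED
    for mod in p.mods:
        relevant = [lad for rmods, lad in rival_ladders if mod not in rmods]
        evidence: set[tuple[str, int]] = set()
        ok = True
        for lad in relevant:
            excluders = [
                m for m in good
                if abs(own[(m.ion.series, m.ion.index)]
                       - lad[(m.ion.series, m.ion.index)]) > MASS_DISTINCT_EPS
            ]
            if not excluders:
                ok = False
            evidence.update((m.ion.series, m.ion.index) for m in excluders)
        if not relevant:
            evidence = {(m.ion.series, m.ion.index) for m in good}
        localization[mod] = tuple(
            m for m in good if (m.ion.series, m.ion.index) in evidence
        )
        if not ok:
            status = REJECTED_AMBIGUOUS
    return replace(psm, status=status, localization=localization)


# --- spectrum-level driver ------------------------------------------------

@dataclass
class SearchResult:
    """Best PSM for one spectrum plus its accepted co-isolated isobars."""

    psm: PSM
    candidates: list[Proteoform]
    cohort: list[PSM]

    @property
    def accepted(self) -> list[PSM]:
        out = [self.psm] if self.psm.status == ACCEPTED else []
        out.extend(p for p in self.cohort if p.status == ACCEPTED)
        return out


def _filter_against_matrix(
    psm: PSM,
    ladder_matrix: np.ndarray,
    rival_modsets: list[frozenset[Modification]],
    self_row: int | None,
    n_residues: int,
    cfg: SearchConfig,
) -> PSM:
    """Vectorized :func:`isoscale_filter` against pre-stacked rival ladders.

    ``ladder_matrix`` holds one row per rival in c1..c(n-1), z1..z(n-1)
    column order; ``self_row`` marks the candidate's own row, if present.
    Same accept/reject semantics as the object-based filter: every rival
    placement of every mod must be excluded by a matched discriminating
    ion within the ppm tolerance.
    """
    if not psm.matches:
        return replace(psm, status=REJECTED_SCORE, localization={})
    if not psm.proteoform.mods:
        return replace(psm, status=ACCEPTED, localization={})
    own = _ladder_mass_array(psm.proteoform, cfg.scheme)

    def col(m: FragmentMatch) -> int:
        return (m.ion.index - 1) if m.ion.series == "c" else (n_residues - 1 + m.ion.index - 1)

    good = [
        m for m in psm.matches
        if abs(m.error_ppm) <= cfg.fragment_tol_filter_ppm
    ]
    gcols = np.array([col(m) for m in good], dtype=int)
    localization: dict[Modification, tuple[FragmentMatch, ...]] = {}
    status = ACCEPTED
    for mod in psm.proteoform.mods:
        rows = [
            i
            for i, ms in enumerate(rival_modsets)
            if i != self_row and mod not in ms
        ]
        if not rows:
            localization[mod] = tuple(good)
            continue
        if gcols.size == 0:
            localization[mod] = ()
            status = REJECTED_AMBIGUOUS
            continue
        # discrim[r, j]: matched ion j excludes rival r
        discrim = (
            np.abs(ladder_matrix[np.ix_(rows, gcols)] - own[gcols])
            > MASS_DISTINCT_EPS
        )
        if not discrim.any(axis=1).all():
            status = REJECTED_AMBIGUOUS
        ev_cols = discrim.any(axis=0)
        localization[mod] = tuple(
            m for m, keep in zip(good, ev_cols) if keep
        )
    return replace(psm, status=status, localization=localization)


def search_spectrum(
    spectrum: Spectrum, cfg: SearchConfig, tail: TailSequence
) -> SearchResult | None:
    """Search one spectrum: enumerate, rank, localize.

    Candidates in the precursor window are ranked by score (ties: fewer
    mods, then notation).  The winner and every candidate within the
    isobaric window of its mass compete as localization rivals; rivals
    showing evidence in the residual spectrum (peaks the winner left
    unexplained) are filtered in full, and the accepted ones form the
    co-isolated cohort that quantification splits intensity over.
    Returns None when no candidate fits the precursor window.
    """
    candidates = enumerate_candidates(spectrum.precursor_neutral_mass, cfg, tail)
    if not candidates:
        return None
    pm = np.array([m for m, _ in spectrum.peaks])
    pi = np.array([i for _, i in spectrum.peaks])
    total = spectrum.total_intensity
    ladders = [_ladder_mass_array(c, cfg.scheme) for c in candidates]
    masses = [proteoform_mass(c, cfg.scheme) for c in candidates]
    scored = sorted(
        range(len(candidates)),
        key=lambda i: (
            -_quick_score(pm, pi, total, ladders[i], cfg.fragment_tol_search),
            len(candidates[i].mods),
            candidates[i].notation,
            candidates[i].channel,
        ),
    )
    bi = scored[0]
    best = candidates[bi]
    rival_idx = [
        i for i in range(len(candidates))
        if abs(masses[i] - masses[bi]) <= cfg.isobaric_window
    ]
    rivals = [candidates[i] for i in rival_idx]
    ladder_matrix = np.stack([ladders[i] for i in rival_idx])
    rival_modsets = [frozenset(candidates[i].mods) for i in rival_idx]
    row_of = {i: r for r, i in enumerate(rival_idx)}
    n = len(tail)

    def full_psm(p: Proteoform) -> PSM:
        matched = match_fragments(
            spectrum, p, cfg.fragment_tol_search, "Da", cfg.scheme
        )
        return PSM(
            spectrum_id=spectrum.id,
            proteoform=p,
            matches=matched,
            score=score_psm(matched, p, spectrum, cfg.scheme),
        )

    best_psm = full_psm(best)
    psm = _filter_against_matrix(
        best_psm, ladder_matrix, rival_modsets, row_of.get(bi), n, cfg
    )
    # residual spectrum: peaks the winner did not explain nominate cohort members
    matched_peaks = {m.peak_index for m in best_psm.matches}
    residual = [k for k in range(len(pm)) if k not in matched_peaks]
    cohort: list[PSM] = []
    if residual:
        rm, ri = pm[residual], pi[residual]
        rtotal = float(ri.sum())
        for r, i in zip(rivals, rival_idx):
            if i == bi:
                continue
            if _quick_score(rm, ri, rtotal, ladders[i], cfg.fragment_tol_search) <= 0:
                continue
            rp = _filter_against_matrix(
                full_psm(r), ladder_matrix, rival_modsets, row_of.get(i), n, cfg
            )
            if rp.status == ACCEPTED and rp.score > 0:
                cohort.append(rp)
    return SearchResult(psm=psm, candidates=candidates, cohort=cohort)


def search_spectra(
    spectra: list[Spectrum], cfg: SearchConfig, tail: TailSequence
) -> list[SearchResult]:
    out = []
    for s in spectra:
        r = search_spectrum(s, cfg, tail)
        if r is not None:
            out.append(r)
    return out
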