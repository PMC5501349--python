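"""Synthetic middle-down data with ground truth.

The generator emulates what the instrument hands the pipeline: GluC
histone tails carrying combinatorial me1/me2/me3/ac marks, optionally
heavy-KR labeled and carrying 0..k heavy methyls per mark, fragmented by
ETD into deconvoluted neutral-mass spectra.  Co-isolated isobaric forms
are merged into single mixed spectra, the situation FIRR exists for.

Three layers of realism are modeled, each optional and seed-deterministic:
multiplicative log-normal fragment-intensity noise (given as a CV),
Bernoulli peak dropout (missing ions), and Gaussian ppm mass jitter.
Fragment base intensities are uniform across ions.  What is *not*
modeled: chromatographic elution, isotope envelopes, charge-state
distributions — the spectra are already deconvoluted neutral masses.

The incomplete-incorporation model captures that long sequences hardly
reach 100% heavy-KR labeling: each K/R site is heavy independently with
probability p, giving an exact binomial label-count/mass-shift
distribution.  The EMT-style time course models methyl turnover: each
methyl group present on a tail is heavy with probability 1 - exp(-λt),
so a k-fold methyl carries Binomial(k, 1 - exp(-λt)) heavy methyls;
confluent (contact-inhibited) cultures are simply a smaller λ.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DEFAULT_SCHEME,
    H3_TAIL,
    LIGHT,
    MOD_KINDS,
    LabelScheme,
    Proteoform,
    Spectrum,
    TailSequence,
    ion_ladder,
    make_proteoform,
    proteoform_mass,
)

__all__ = [
    "NoiseModel",
    "MixtureSpec",
    "GroundTruth",
    "IncorporationModel",
    "simulate_spectra",
    "simulate_incorporation",
    "simulate_emt_timecourse",
    "default_h3_marginals",
]


@dataclass(frozen=True)
class NoiseModel:
    """Fragment-level noise: intensity CV (log-normal, mean-preserving),
    peak dropout probability, and mass jitter sd in ppm."""

    intensity_cv: float = 0.0
    dropout: float = 0.0
    mass_jitter_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.mass_jitter_ppm < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class MixtureSpec:
    """A proteoform mixture with known proportions.

    ``components`` is a list of (notation, channel, proportion); the
    proportions must be positive and sum to 1.  ``time`` is the labeling
    time in days (carried for provenance; spectra themselves are
    time-free).
    """

    tail: TailSequence = H3_TAIL
    components: tuple[tuple[str, str, float], ...] = ()
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    time: float = 0.0
    base_intensity: float = 1000.0
    charge: int = 8
    isobaric_window: float = 0.05

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        props = [p for _, _, p in self.components]
        if any(p <= 0 for p in props):
            raise ValueError("proportions must be > 0")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.time < 0:
            raise ValueError("labeling time must be >= 0")

    def proteoforms(self) -> list[tuple[Proteoform, float]]:
        return [
            (make_proteoform(self.tail, notation, channel), prop)
            for notation, channel, prop in self.components
        ]


@dataclass
class GroundTruth:
    """What the simulator actually put into the spectra."""

    spec: MixtureSpec
    spectrum_members: dict[str, list[tuple[Proteoform, float]]]
    expected_table: pd.DataFrame
    seed: int = 0


def _expected_table(spec: MixtureSpec, sample: str = "truth") -> pd.DataFrame:
    rows = []
    for p, prop in spec.proteoforms():
        rows.append(
            {
                "tail": p.tail.name,
                "proteoform": p.notation,
                "channel": p.channel,
                "sample": sample,
                "intensity": prop * spec.base_intensity,
            }
        )
    df = pd.DataFrame(rows)
    totals = df.groupby(["tail", "channel", "sample"])["intensity"].transform("sum")
    df["relative_abundance"] = df["intensity"] / totals
    return df


def simulate_spectra(
    spec: MixtureSpec, scheme: LabelScheme = DEFAULT_SCHEME
) -> tuple[list[Spectrum], GroundTruth]:
    """Emit one mixed spectrum per isobaric group of the mixture.

    Peaks are the exact c/z• ladders of the group members, each ion at
    base_intensity x the member's proportion; ions with identical mass
    (shared between members) accumulate.  Noise is then applied
    peak-wise.  Reproducible: the same spec (including seed) gives
    byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    members = spec.proteoforms()
    masses = [proteoform_mass(p, scheme) for p, _ in members]
    order = sorted(range(len(members)), key=lambda i: masses[i])
    groups: list[list[int]] = []
    for i in order:
        if groups and masses[i] - masses[groups[-1][-1]] <= spec.isobaric_window:
            groups[-1].append(i)
        else:
            groups.append([i])

    spectra: list[Spectrum] = []
    by_spectrum: dict[str, list[tuple[Proteoform, float]]] = {}
    for gi, idxs in enumerate(groups):
        peak_acc: dict[float, float] = {}
        for i in idxs:
            p, prop = members[i]
            for ion in ion_ladder(p, scheme):
                key = round(ion.neutral_mass, 6)
                peak_acc[key] = peak_acc.get(key, 0.0) + prop * spec.base_intensity
        peaks = sorted(peak_acc.items())
        nm = np.array([m for m, _ in peaks])
        ni = np.array([x for _, x in peaks])
        n = spec.noise
        if n.intensity_cv > 0:
            sigma = np.sqrt(np.log1p(n.intensity_cv**2))
            ni = ni * rng.lognormal(-sigma**2 / 2, sigma, size=ni.size)
        if n.dropout > 0:
            keep = rng.random(ni.size) >= n.dropout
            nm, ni = nm[keep], ni[keep]
        if n.mass_jitter_ppm > 0:
            nm = nm + rng.normal(0.0, n.mass_jitter_ppm * 1e-6 * nm)
        total_prop = sum(members[i][1] for i in idxs)
        precursor = sum(masses[i] * members[i][1] for i in idxs) / total_prop
        sid = f"{spec.tail.name}_g{gi}"
        spectra.append(
            Spectrum(
                id=sid,
                precursor_neutral_mass=precursor,
                precursor_charge=spec.charge,
                peaks=list(zip(nm.tolist(), ni.tolist())),
            )
        )
        by_spectrum[sid] = [members[i] for i in idxs]
    truth = GroundTruth(
        spec=spec,
        spectrum_members=by_spectrum,
        expected_table=_expected_table(spec),
        seed=spec.seed,
    )
    return spectra, truth


# --- incomplete heavy-KR incorporation ------------------------------------

@dataclass(frozen=True)
class IncorporationModel:
    """Independent per-site heavy incorporation with probability p over
    n_lysines + n_arginines labelable residues."""

    p: float
    n_lysines: int
    n_arginines: int

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("incorporation probability must be in [0, 1]")
        if self.n_lysines < 0 or self.n_arginines < 0:
            raise ValueError("site counts must be >= 0")

    @classmethod
    def from_tail(cls, tail: TailSequence, p: float = 0.95) -> "IncorporationModel":
        return cls(p, len(tail.sites_of("K")), len(tail.sites_of("R")))

    @property
    def n_sites(self) -> int:
        return self.n_lysines + self.n_arginines


def simulate_incorporation(
    model: IncorporationModel, scheme: LabelScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Exact label-count distribution (no sampling).

    Heavy K and R counts are independent binomials; the joint pmf is
    aggregated into rows (n_heavy, mass_shift, probability).  At p=1 the
    distribution is a point mass at the full shift; the mean shift is
    p x full shift by linearity.
    """
    kk = np.arange(model.n_lysines + 1)
    rr = np.arange(model.n_arginines + 1)
    pk = stats.binom.pmf(kk, model.n_lysines, model.p)
    pr = stats.binom.pmf(rr, model.n_arginines, model.p)
    rows: dict[tuple[int, float], float] = {}
    for k, pkv in zip(kk, pk):
        for r, prv in zip(rr, pr):
            shift = round(
                k * scheme.heavy_K_delta + r * scheme.heavy_R_delta, 9
            )
            key = (int(k + r), shift)
            rows[key] = rows.get(key, 0.0) + float(pkv * prv)
    df = pd.DataFrame(
        [
            {"n_heavy": n, "mass_shift": s, "probability": p}
            for (n, s), p in sorted(rows.items())
            if p > 0.0
        ]
    )
    return df.reset_index(drop=True)


# --- EMT-style heavy-methyl time course -----------------------------------

def default_h3_marginals() -> dict[int, dict[str, float]]:
    """Per-site single-mark marginals for the nine H3 sites.

    Chosen once as a realistic steady-state histone H3 profile: K9/K27/K36
    heavily methylated, K14/K18/K23 mostly acetylation-prone, sparse
    K4/R8/R26 marks.  The empty-string state is unmodified.
    """
    return {
        4: {"": 0.85, "me1": 0.10, "me2": 0.03, "me3": 0.02},
        8: {"": 0.90, "me1": 0.07, "me2": 0.03},
        9: {"": 0.35, "me1": 0.25, "me2": 0.20, "me3": 0.15, "ac": 0.05},
        14: {"": 0.55, "ac": 0.35, "me1": 0.05, "me2": 0.03, "me3": 0.02},
        18: {"": 0.75, "ac": 0.15, "me1": 0.08, "me2": 0.02},
        23: {"": 0.60, "ac": 0.20, "me1": 0.15, "me2": 0.05},
        26: {"": 0.80, "me1": 0.15, "me2": 0.05},
        27: {"": 0.25, "me1": 0.25, "me2": 0.30, "me3": 0.18, "ac": 0.02},
        36: {"": 0.45, "me1": 0.20, "me2": 0.25, "me3": 0.10},
    }


#: default first-order methyl replacement rates (per day); confluent
#: cultures turn methyls over more slowly (contact inhibition)
LAMBDA_NONCONFLUENT = 0.5
LAMBDA_CONFLUENT = 0.22


def simulate_emt_timecourse(
    lam: float = LAMBDA_NONCONFLUENT,
    times: tuple[float, ...] = (0.0, 1.0, 2.0),
    marginals: dict[int, dict[str, float]] | None = None,
    tail: TailSequence = H3_TAIL,
    n_tails: int = 10_000,
    seed: int = 0,
    sample_prefix: str = "day",
) -> dict[float, pd.DataFrame]:
    """Sample combinatorial quant tables across a labeling time course.

    Each of ``n_tails`` tails draws one state per site from the marginals
    (sites independent); each methyl group then turns heavy with
    probability 1 - exp(-lam*t), so a k-methyl mark carries
    Binomial(k, 1 - exp(-lam*t)) heavy methyls.  Returns one normalized
    quant table per time point (intensity = tail counts).
    """
    if lam < 0:
        raise ValueError("turnover rate must be >= 0")
    marg = marginals if marginals is not None else default_h3_marginals()
    rng = np.random.default_rng(seed)
    sites = sorted(marg)
    out: dict[float, pd.DataFrame] = {}
    for t in times:
        q = 1.0 - np.exp(-lam * t)
        tokens_per_site: list[np.ndarray] = []
        for site in sites:
            residue = tail.residue_at(site)
            states = list(marg[site])
            probs = np.array([marg[site][s] for s in states])
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"marginals at site {site} do not sum to 1")
            draw = rng.choice(len(states), size=n_tails, p=probs)
            toks = np.empty(n_tails, dtype=object)
            for si, state in enumerate(states):
                mask = draw == si
                if not state:
                    toks[mask] = ""
                    continue
                k = MOD_KINDS[state]
                if k == 0 or q == 0.0:
                    toks[mask] = f"{residue}{site}{state}"
                else:
                    h = rng.binomial(k, q, size=int(mask.sum()))
                    base = f"{residue}{site}{state}"
                    toks[mask] = np.array(
                        [base + (f":{hv}" if hv else "") for hv in h],
                        dtype=object,
                    )
            tokens_per_site.append(toks)
        notations = np.array(
            ["".join(parts) for parts in zip(*tokens_per_site)], dtype=object
        )
        counts = pd.Series(notations).value_counts().sort_index()
        df = pd.DataFrame(
            {
                "tail": tail.name,
                "proteoform": counts.index,
                "channel": LIGHT,
                "sample": f"{sample_prefix}{t:g}",
                "intensity": counts.to_numpy(dtype=float),
            }
        )
        df["relative_abundance"] = df["intensity"] / df["intensity"].sum()
        out[t] = df.reset_index(drop=True)
    return out
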