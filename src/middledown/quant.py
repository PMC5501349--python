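"""FIRR quantification and relative abundance.

Imperfect chromatographic separation of middle-down tails means isobaric
proteoforms — same mass, marks on different sites — are co-isolated and
fragmented together.  The fragment ion relative ratio (FIRR) approach
splits the shared MS/MS intensity among the co-isolated forms in
proportion to the relative intensities of their site-determining fragment
ions: ions unique to one placement report on that member's share only,
while shared ions carry mixed signal and are ignored for the split.

Relative abundance then normalizes each proteoform's intensity by the
summed intensity of all modified and unmodified forms sharing the same
tail sequence, per label channel and sample (a pooled mode normalizes the
two channels together).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import (
    DEFAULT_SCHEME,
    FragmentIon,
    LabelScheme,
    Proteoform,
    ion_ladder,
)
from .search import ACCEPTED, MASS_DISTINCT_EPS, PSM, SearchResult

logger = logging.getLogger(__name__)

QUANT_COLUMNS = ["tail", "proteoform", "channel", "sample", "intensity", "relative_abundance"]


@dataclass(frozen=True)
class QuantRecord:
    """One quantified proteoform in one channel of one sample."""

    tail: str
    proteoform: str
    channel: str
    sample: str
    intensity: float
    relative_abundance: float = float("nan")

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


def records_to_frame(records: list[QuantRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=QUANT_COLUMNS)


def member_specific_ions(
    members: list[Proteoform], scheme: LabelScheme = DEFAULT_SCHEME
) -> dict[Proteoform, tuple[FragmentIon, ...]]:
    """Ions unique to each member of an isobaric group: theoretical mass
    differs from the corresponding ion of every other member."""
    ladders = {m: ion_ladder(m, scheme) for m in members}
    by_key = {
        m: {(i.series, i.index): i.neutral_mass for i in lad}
        for m, lad in ladders.items()
    }
    out: dict[Proteoform, tuple[FragmentIon, ...]] = {}
    for m in members:
        others = [by_key[o] for o in members if o is not m]
        out[m] = tuple(
            ion
            for ion in ladders[m]
            if all(
                abs(ion.neutral_mass - o[(ion.series, ion.index)]) > MASS_DISTINCT_EPS
                for o in others
            )
        )
    return out


@dataclass
class IsobaricGroup:
    """Co-isolated isobaric proteoforms sharing one spectrum's intensity.

    ``sd_intensities`` holds, per member, the observed intensities of its
    matched site-determining ions — the positions where the members
    actually differ.
    """

    members: tuple[Proteoform, ...]
    total_intensity: float
    sd_intensities: dict[Proteoform, tuple[float, ...]]

    def __post_init__(self) -> None:
        if self.total_intensity < 0:
            raise ValueError("total intensity must be >= 0")


def group_from_psms(
    psms: list[PSM], scheme: LabelScheme = DEFAULT_SCHEME
) -> IsobaricGroup:
    """Build an isobaric group from the accepted PSMs of one spectrum.

    The shared total is the summed intensity of every peak matched by any
    member (each spectrum peak counted once); per-member site-determining
    intensities come from the matches falling on its member-specific ions.
    """
    members = [p.proteoform for p in psms]
    spec_ions = member_specific_ions(members, scheme)
    sd: dict[Proteoform, tuple[float, ...]] = {}
    seen_peaks: set[int] = set()
    total = 0.0
    for psm in psms:
        keys = {(i.series, i.index) for i in spec_ions[psm.proteoform]}
        sd[psm.proteoform] = tuple(
            m.peak_intensity
            for m in psm.matches
            if (m.ion.series, m.ion.index) in keys
        )
        for m in psm.matches:
            if m.peak_index not in seen_peaks:
                seen_peaks.add(m.peak_index)
                total += m.peak_intensity
    return IsobaricGroup(tuple(members), total, sd)


def firr_split(group: IsobaricGroup) -> dict[Proteoform, float]:
    """Split the group's total intensity among its members.

    Each member's raw weight is the mean intensity of its matched
    site-determining ions; shares are the weights normalized to the
    group total.  Exact when intensities are noise-free, because every
    site-determining ion of a member then carries exactly that member's
    proportion of the base signal.  A member with no site-determining
    signal gets share 0 (logged); a singleton keeps the whole total.
    """
    if len(group.members) == 1:
        return {group.members[0]: group.total_intensity}
    raw: dict[Proteoform, float] = {}
    for m in group.members:
        ints = group.sd_intensities.get(m, ())
        if not ints:
            logger.warning(
                "no site-determining signal for %s; share set to 0", m.notation
            )
            raw[m] = 0.0
        else:
            raw[m] = sum(ints) / len(ints)
    denom = sum(raw.values())
    if denom == 0:
        raise ValueError("no member of the isobaric group has any signal")
    return {m: w / denom * group.total_intensity for m, w in raw.items()}


def relative_abundance(table: pd.DataFrame, pooled: bool = False) -> pd.DataFrame:
    """Add ``relative_abundance`` = intensity / group total.

    Groups are (tail, channel, sample) — light and heavy tails are
    distinct sequences — unless ``pooled``, which normalizes both
    channels of a tail together.  Rows of the same proteoform (multiple
    PSMs) are summed before normalizing.
    """
    needed = {"tail", "proteoform", "channel", "sample", "intensity"}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"quant table missing columns {sorted(missing)}")
    keys = ["tail", "sample"] if pooled else ["tail", "channel", "sample"]
    df = table.groupby(
        ["tail", "channel", "sample", "proteoform"], as_index=False
    )["intensity"].sum()
    totals = df.groupby(keys)["intensity"].transform("sum")
    if (totals == 0).any():
        raise ValueError("zero total intensity in a normalization group")
    df = df.copy()
    df["relative_abundance"] = df["intensity"] / totals
    return df[[c for c in QUANT_COLUMNS if c in df.columns]]


def channel_ratio(light: float, heavy: float) -> float:
    """Raw heavy/light intensity ratio; NaN (logged) when light is 0."""
    if light == 0:
        logger.warning("light intensity is 0; channel ratio undefined")
        return float("nan")
    return heavy / light


def channel_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Per-proteoform heavy/light intensity ratios within each sample."""
    piv = table.pivot_table(
        index=["tail", "proteoform", "sample"],
        columns="channel",
        values="intensity",
        aggfunc="sum",
    )
    out = piv.reset_index()
    light = out.get("light", pd.Series(0.0, index=out.index))
    heavy = out.get("heavy_KR", pd.Series(0.0, index=out.index))
    out["ratio"] = [channel_ratio(l, h) for l, h in zip(light, heavy)]
    out["defined"] = light > 0
    return out[["tail", "proteoform", "sample", "ratio", "defined"]]


PSM_COLUMNS = [
    "spectrum_id", "tail", "proteoform", "channel", "mass", "score", "status",
    "n_matched", "max_ppm_error", "matched_intensity", "sd_intensity_mean",
    "group_total_intensity",
]


def results_to_psm_frame(
    results: list[SearchResult], scheme: LabelScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Flatten search results to the PSM TSV schema.

    Accepted co-isolated isobars of one spectrum share a
    ``group_total_intensity`` and carry their mean site-determining ion
    intensity, so FIRR splitting can be redone from the table alone.
    """
    from .model import proteoform_mass

    rows = []
    for res in results:
        accepted = res.accepted
        group = group_from_psms(accepted, scheme) if len(accepted) > 1 else None
        psms = [res.psm] + [c for c in res.cohort if c is not res.psm]
        for psm in psms:
            sd_mean = float("nan")
            gtotal = psm.matched_intensity
            if group is not None and psm.proteoform in group.sd_intensities:
                ints = group.sd_intensities[psm.proteoform]
                sd_mean = sum(ints) / len(ints) if ints else 0.0
                gtotal = group.total_intensity
            rows.append(
                {
                    "spectrum_id": psm.spectrum_id,
                    "tail": psm.proteoform.tail.name,
                    "proteoform": psm.proteoform.notation,
                    "channel": psm.proteoform.channel,
                    "mass": proteoform_mass(psm.proteoform, scheme),
                    "score": psm.score,
                    "status": psm.status,
                    "n_matched": psm.n_matched,
                    "max_ppm_error": psm.max_ppm_error,
                    "matched_intensity": psm.matched_intensity,
                    "sd_intensity_mean": sd_mean,
                    "group_total_intensity": gtotal,
                }
            )
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


def quantify_psm_frame(
    psms: pd.DataFrame, sample: str = "sample1", pooled: bool = False
) -> pd.DataFrame:
    """Quantify from a PSM table (the TSV written by the search stage).

    Accepted PSMs only.  Spectra with one accepted proteoform contribute
    their matched intensity; spectra with several split the group total
    by the stored site-determining intensity means (the FIRR weights).
    """
    psms = psms.copy()
    # the unmodified proteoform serializes as an empty string
    psms["proteoform"] = psms["proteoform"].fillna("")
    acc = psms[psms["status"] == ACCEPTED]
    if acc.empty:
        raise ValueError("no accepted PSMs to quantify")
    rows = []
    for _, sub in acc.groupby("spectrum_id"):
        if len(sub) == 1:
            r = sub.iloc[0]
            shares = {(r["tail"], r["proteoform"], r["channel"]): r["matched_intensity"]}
        else:
            w = sub["sd_intensity_mean"].fillna(0.0).to_numpy(dtype=float)
            if w.sum() == 0:
                raise ValueError(
                    f"no site-determining signal in spectrum {sub.iloc[0]['spectrum_id']}"
                )
            total = float(sub["group_total_intensity"].iloc[0])
            shares = {
                (r["tail"], r["proteoform"], r["channel"]): wi / w.sum() * total
                for (_, r), wi in zip(sub.iterrows(), w)
                if wi > 0
            }
        for (tail, pf, channel), intensity in shares.items():
            rows.append(
                {
                    "tail": tail,
                    "proteoform": pf,
                    "channel": channel,
                    "sample": sample,
                    "intensity": intensity,
                }
            )
    return relative_abundance(pd.DataFrame(rows), pooled=pooled)


def quantify_search_results(
    results: list[SearchResult],
    sample: str = "sample1",
    scheme: LabelScheme = DEFAULT_SCHEME,
    pooled: bool = False,
) -> pd.DataFrame:
    """Turn accepted search results into a normalized quant table.

    Spectra with a single accepted proteoform contribute their matched
    intensity directly; spectra with accepted co-isolated isobars are
    FIRR-split first.  Intensities are summed per proteoform across
    spectra, then normalized per (tail, channel, sample).
    """
    rows = []
    for res in results:
        accepted = res.accepted
        if not accepted:
            continue
        if len(accepted) == 1:
            shares = {accepted[0].proteoform: accepted[0].matched_intensity}
        else:
            # zero-share members are placements the fragment evidence does
            # not support (phantom combinations of the co-isolated forms)
            shares = {
                p: v
                for p, v in firr_split(group_from_psms(accepted, scheme)).items()
                if v > 0
            }
        for p, intensity in shares.items():
            rows.append(
                {
                    "tail": p.tail.name,
                    "proteoform": p.notation,
                    "channel": p.channel,
                    "sample": sample,
                    "intensity": intensity,
                }
            )
    if not rows:
        raise ValueError("no accepted identifications to quantify")
    return relative_abundance(pd.DataFrame(rows), pooled=pooled)
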