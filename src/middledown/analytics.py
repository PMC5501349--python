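"""Combinatorial PTM analytics on normalized quant tables.

Everything here consumes the quant-table DataFrame produced by
:mod:`middledown.quant` (columns tail, proteoform, channel, sample,
intensity, relative_abundance) and deconvolutes it into single-mark
quantities:

* single-mark abundance — the summed relative abundance of every
  combinatorial form carrying a given mark (the remaining share, up to 1,
  is the unmodified state of that site);
* heavy fraction — the share of tails carrying at least one heavy
  (13CD3) methyl group, the turnover readout of pulse labeling;
* hybrid marks — marks only partially heavy (0 < h < k), which separate
  regulated methylation-state changes from plain turnover;
* interplay scores — log2(observed / expected) co-occurrence of two
  marks, positive when they coexist more often than chance, negative when
  they tend to exclude each other;
* replicate statistics — Pearson correlation with t-test p-values and
  per-mark coefficients of variation.

Mark keys use the proteoform notation grammar: ``K27me2`` is the fully
light mark (h=0), ``K27me2:1`` one heavy methyl, ``K27me2:*`` aggregates
over heavy counts.
"""
from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import MOD_KINDS, NotationError, iter_tokens

_MARK_RE = re.compile(r"([A-Z])(\d+)(me[123]|ac)(?::(\d+|\*))?$")


@dataclass(frozen=True)
class MarkKey:
    """One single-mark selector; ``heavy=None`` is the ``:*`` wildcard."""

    site: int
    residue: str
    kind: str
    heavy: int | None = 0

    def __post_init__(self) -> None:
        if self.kind not in MOD_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        k = MOD_KINDS[self.kind]
        if self.heavy is not None and not 0 <= self.heavy <= k:
            raise ValueError(f"heavy count {self.heavy} outside 0..{k}")

    @classmethod
    def parse(cls, s: str) -> "MarkKey":
        m = _MARK_RE.match(s.strip())
        if m is None:
            raise NotationError(f"malformed mark key {s!r}")
        residue, site, kind, heavy = m.groups()
        h: int | None
        if heavy == "*":
            h = None
        elif heavy is None:
            h = 0
        else:
            h = int(heavy)
        return cls(int(site), residue, kind, h)

    def matches(self, token: tuple[str, int, str, int]) -> bool:
        residue, site, kind, heavy = token
        if (residue, site, kind) != (self.residue, self.site, self.kind):
            return False
        return self.heavy is None or heavy == self.heavy

    def __str__(self) -> str:
        s = f"{self.residue}{self.site}{self.kind}"
        if self.heavy is None:
            return s + ":*"
        return s + (f":{self.heavy}" if self.heavy else "")


def _as_key(key: "MarkKey | str") -> MarkKey:
    return key if isinstance(key, MarkKey) else MarkKey.parse(key)


def _check_normalized(table: pd.DataFrame) -> pd.DataFrame:
    if "relative_abundance" not in table.columns:
        raise ValueError("table is not normalized (no relative_abundance column)")
    return table


def proteoform_contains(notation: str, key: MarkKey) -> bool:
    return any(key.matches(tok) for tok in iter_tokens(notation))


def single_ptm_abundance(table: pd.DataFrame, key: "MarkKey | str") -> float:
    """Summed relative abundance of all forms carrying the mark."""
    key = _as_key(key)
    t = _check_normalized(table)
    mask = t["proteoform"].map(lambda n: proteoform_contains(n, key))
    return float(t.loc[mask, "relative_abundance"].sum())


def observed_marks(table: pd.DataFrame, wildcard: bool = False) -> list[MarkKey]:
    """Distinct mark keys present in the table, site-ascending."""
    seen: set[MarkKey] = set()
    for n in table["proteoform"].unique():
        for residue, site, kind, heavy in iter_tokens(n):
            seen.add(MarkKey(site, residue, kind, None if wildcard else heavy))
    return sorted(seen, key=lambda k: (k.site, k.kind, k.heavy if k.heavy is not None else -1))


def heavy_fraction(table: pd.DataFrame) -> float:
    """Share of tails carrying at least one heavy methyl group."""
    t = _check_normalized(table)
    mask = t["proteoform"].map(
        lambda n: sum(h for _, _, _, h in iter_tokens(n)) >= 1
    )
    return float(t.loc[mask, "relative_abundance"].sum())


def hybrid_marks(table: pd.DataFrame) -> list[tuple[MarkKey, float]]:
    """Partially heavy marks (0 < h < k), ranked by summed abundance.

    Fully heavy marks are excluded: they are indistinguishable from plain
    turnover, while hybrids prove a site kept part of its pre-label
    methylation state and gained new methyls afterwards.
    """
    t = _check_normalized(table)
    acc: dict[MarkKey, float] = {}
    for notation, ab in zip(t["proteoform"], t["relative_abundance"]):
        for residue, site, kind, heavy in iter_tokens(notation):
            if 0 < heavy < MOD_KINDS[kind]:
                k = MarkKey(site, residue, kind, heavy)
                acc[k] = acc.get(k, 0.0) + float(ab)
    return sorted(acc.items(), key=lambda kv: (-kv[1], str(kv[0])))


@dataclass(frozen=True)
class InterplayResult:
    """Co-occurrence of two marks versus independence.

    ``score`` = log2(F_ab / (F_a * F_b)); positive when the marks ride the
    same tails more often than chance, negative when they avoid each
    other.  ``defined`` is False when any frequency is 0 (the mutually
    exclusive sentinel), keeping ranked outputs sortable without -inf.
    """

    mark_a: MarkKey
    mark_b: MarkKey
    f_a: float
    f_b: float
    f_ab: float
    score: float
    defined: bool


def interplay(
    table: pd.DataFrame, a: "MarkKey | str", b: "MarkKey | str"
) -> InterplayResult:
    """Interplay score of two marks on different sites."""
    a, b = _as_key(a), _as_key(b)
    if a.site == b.site:
        raise ValueError(f"marks {a} and {b} share site {a.site}")
    t = _check_normalized(table)
    f_a = f_b = f_ab = 0.0
    for notation, ab in zip(t["proteoform"], t["relative_abundance"]):
        toks = list(iter_tokens(notation))
        has_a = any(a.matches(tok) for tok in toks)
        has_b = any(b.matches(tok) for tok in toks)
        if has_a:
            f_a += ab
        if has_b:
            f_b += ab
        if has_a and has_b:
            f_ab += ab
    defined = f_a > 0 and f_b > 0 and f_ab > 0
    score = math.log2(f_ab / (f_a * f_b)) if defined else float("nan")
    return InterplayResult(a, b, float(f_a), float(f_b), float(f_ab), score, defined)


def interplay_table(
    table: pd.DataFrame, keys: list["MarkKey | str"] | None = None
) -> pd.DataFrame:
    """All pairwise interplay scores among the given (or observed) marks."""
    marks = [_as_key(k) for k in keys] if keys else observed_marks(table)
    rows = []
    for a, b in itertools.combinations(marks, 2):
        if a.site == b.site:
            continue
        r = interplay(table, a, b)
        rows.append(
            {
                "mark_a": str(r.mark_a),
                "mark_b": str(r.mark_b),
                "f_a": r.f_a,
                "f_b": r.f_b,
                "f_ab": r.f_ab,
                "score": r.score,
                "defined": r.defined,
            }
        )
    return pd.DataFrame(
        rows, columns=["mark_a", "mark_b", "f_a", "f_b", "f_ab", "score", "defined"]
    )


def replicate_correlation(x, y) -> tuple[float, float]:
    """Pearson r between paired abundance vectors with its two-tailed
    t-test p-value (t = r sqrt((n-2)/(1-r^2)), n-2 df).  Returns
    (nan, nan) when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cv_by_mark(
    replicate_tables: list[pd.DataFrame],
    keys: list["MarkKey | str"] | None = None,
) -> pd.DataFrame:
    """Coefficient of variation (sd/mean, sample sd) of single-mark
    abundances across replicates; NaN where the mean is 0."""
    if len(replicate_tables) < 2:
        raise ValueError("need at least 2 replicate tables")
    if keys is None:
        seen: dict[MarkKey, None] = {}
        for t in replicate_tables:
            for k in observed_marks(t):
                seen.setdefault(k, None)
        marks = list(seen)
    else:
        marks = [_as_key(k) for k in keys]
    rows = []
    for k in marks:
        vals = np.array([single_ptm_abundance(t, k) for t in replicate_tables])
        mean = vals.mean()
        cv = float(vals.std(ddof=1) / mean) if mean > 0 else float("nan")
        rows.append(
            {
                "mark": str(k),
                "site": k.site,
                "kind": k.kind,
                "mean": float(mean),
                "cv": cv,
            }
        )
    return pd.DataFrame(rows, columns=["mark", "site", "kind", "mean", "cv"])


def cv_grouped(cv_table: pd.DataFrame, by: str = "site") -> pd.Series:
    """Average CV grouped by modification ``site`` or ``kind``."""
    if by not in ("site", "kind"):
        raise ValueError("group by 'site' or 'kind'")
    return cv_table.groupby(by)["cv"].mean()


def compare_single_mark_tables(
    t1: "pd.Series | dict[str, float]", t2: "pd.Series | dict[str, float]"
) -> tuple[float, float, float]:
    """Compare two single-mark abundance tables on their shared marks.

    Returns (least-squares slope through the origin, Pearson r, p).
    Built for middle-down vs bottom-up style cross-method checks.
    """
    s1, s2 = pd.Series(t1, dtype=float), pd.Series(t2, dtype=float)
    shared = s1.index.intersection(s2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared mark keys")
    x, y = s1[shared].to_numpy(), s2[shared].to_numpy()
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("first table has no signal on the shared marks")
    slope = float(x @ y) / sxx
    r, p = replicate_correlation(x, y)
    return slope, r, p


def single_mark_table(
    table: pd.DataFrame, keys: list["MarkKey | str"] | None = None
) -> pd.DataFrame:
    """Mark-by-sample matrix of single-mark abundances (long format)."""
    marks = [_as_key(k) for k in keys] if keys else observed_marks(table)
    rows = []
    for (channel, sample), sub in table.groupby(["channel", "sample"]):
        for k in marks:
            rows.append(
                {
                    "mark": str(k),
                    "channel": channel,
                    "sample": sample,
                    "abundance": single_ptm_abundance(sub, k),
                }
            )
    return pd.DataFrame(rows, columns=["mark", "channel", "sample", "abundance"])
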