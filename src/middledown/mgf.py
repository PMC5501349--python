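"""MGF peak-list reading and writing.

The dialect is standard BEGIN IONS/END IONS MGF with one extension: a
block-level ``NEUTRAL=1`` flag marks the fragment masses as
already-deconvoluted neutral monoisotopic masses (Xtract-style output,
the default this package writes).  Without the flag, fragment values are
taken as singly protonated m/z.  ``PEPMASS`` is always precursor m/z and
requires ``CHARGE`` to recover the neutral precursor mass.

Writers are deterministic: fixed key order, 6-decimal masses, LF line
endings — identical input gives byte-identical files.
"""
from __future__ import annotations

from pathlib import Path

from .model import PROTON, Spectrum, mz, neutral_mass_from_mz


class MGFError(ValueError):
    """Malformed MGF content; the message carries the 1-based line number."""

    def __init__(self, line_no: int, message: str) -> None:
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra in the neutral-mass dialect (NEUTRAL=1)."""
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.id}")
        lines.append(
            f"PEPMASS={mz(s.precursor_neutral_mass, s.precursor_charge):.6f}"
        )
        lines.append(f"CHARGE={s.precursor_charge}+")
        lines.append("NEUTRAL=1")
        if s.retention_time is not None:
            lines.append(f"RTINSECONDS={s.retention_time:.3f}")
        for m, i in s.peaks:
            lines.append(f"{m:.6f} {i:.6f}")
        lines.append("END IONS")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), newline="\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into spectra.

    Tolerant of blank lines and ``#`` comments; raises :class:`MGFError`
    with the line number on malformed blocks, missing CHARGE, or
    unparsable peak lines.
    """
    spectra: list[Spectrum] = []
    in_block = False
    params: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    begin_line = 0
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise MGFError(ln, "BEGIN IONS inside an open block")
            in_block, params, peaks, begin_line = True, {}, [], ln
            continue
        if line == "END IONS":
            if not in_block:
                raise MGFError(ln, "END IONS without BEGIN IONS")
            spectra.append(_finish_block(params, peaks, begin_line))
            in_block = False
            continue
        if not in_block:
            raise MGFError(ln, f"content outside BEGIN IONS block: {line!r}")
        if "=" in line and not line[0].isdigit():
            key, _, value = line.partition("=")
            params[key.strip().upper()] = value.strip()
            continue
        fields = line.split()
        if len(fields) < 2:
            raise MGFError(ln, f"peak line needs mass and intensity: {line!r}")
        try:
            peaks.append((float(fields[0]), float(fields[1])))
        except ValueError:
            raise MGFError(ln, f"unparsable peak line: {line!r}") from None
    if in_block:
        raise MGFError(begin_line, "unterminated BEGIN IONS block")
    return spectra


def _finish_block(
    params: dict[str, str], peaks: list[tuple[float, float]], begin_line: int
) -> Spectrum:
    if "PEPMASS" not in params:
        raise MGFError(begin_line, "block has no PEPMASS")
    try:
        pepmass = float(params["PEPMASS"].split()[0])
    except ValueError:
        raise MGFError(begin_line, f"bad PEPMASS {params['PEPMASS']!r}") from None
    if "CHARGE" not in params:
        raise MGFError(begin_line, "PEPMASS is m/z but block has no CHARGE")
    cs = params["CHARGE"].rstrip("+")
    try:
        charge = int(cs)
    except ValueError:
        raise MGFError(begin_line, f"bad CHARGE {params['CHARGE']!r}") from None
    neutral_flag = params.get("NEUTRAL", "0") == "1"
    if not neutral_flag:
        peaks = [(m - PROTON, i) for m, i in peaks]
    rt = None
    if "RTINSECONDS" in params:
        try:
            rt = float(params["RTINSECONDS"])
        except ValueError:
            raise MGFError(
                begin_line, f"bad RTINSECONDS {params['RTINSECONDS']!r}"
            ) from None
    return Spectrum(
        id=params.get("TITLE", f"spectrum_{begin_line}"),
        precursor_neutral_mass=neutral_mass_from_mz(pepmass, charge),
        precursor_charge=charge,
        peaks=peaks,
        retention_time=rt,
    )


def write_tsv(df, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Deterministic TSV: UTF-8, LF, '.' decimal, stable row order."""
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
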