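"""Reading, merging and processing of dta MS/MS spectra.

Processing pipeline (applied in this order): charge filter, base-peak
normalization, count-based bin denoising, and the H3PO4 neutral-loss
prescreen that selects candidate phosphopeptide spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import chem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Spectrum:
    """A single MS/MS spectrum as read from a dta record.

    ``precursor_mh`` is the singly-protonated precursor mass (M+H)+ in Da,
    the de-facto dta first-line convention.
    """

    spectrum_id: str
    precursor_mh: float
    charge: int
    peaks: list[Peak]
    normalized: bool = False
    nl_peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mh - chem.PROTON

    @property
    def precursor_mz(self) -> float:
        return chem.mz_from_neutral(self.precursor_neutral_mass, self.charge)

    def sorted_by_mz(self) -> "Spectrum":
        return replace(self, peaks=sorted(self.peaks, key=lambda p: p.mz))


class DtaParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dta I/O
# ---------------------------------------------------------------------------

def _parse_dta_lines(
    lines: Sequence[str], spectrum_id: str, precursor: str = "mh"
) -> Spectrum | None:
    rows = [
        (i, ln.split()) for i, ln in enumerate(lines, start=1) if ln.strip()
    ]
    if not rows:
        raise DtaParseError(f"{spectrum_id}: empty dta record")
    lineno, head = rows[0]
    if len(head) != 2:
        raise DtaParseError(
            f"{spectrum_id} line {lineno}: expected 'precursor charge'"
        )
    try:
        value = float(head[0])
        charge = int(head[1])
    except ValueError as exc:
        raise DtaParseError(f"{spectrum_id} line {lineno}: {exc}") from exc
    if precursor == "mh":
        mh = value
    elif precursor == "mz":
        mh = value * charge - (charge - 1) * chem.PROTON
    else:
        raise ValueError("precursor convention must be 'mh' or 'mz'")
    peaks: list[Peak] = []
    for lineno, parts in rows[1:]:
        if len(parts) != 2:
            raise DtaParseError(
                f"{spectrum_id} line {lineno}: expected 'mz intensity'"
            )
        try:
            peaks.append(Peak(float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise DtaParseError(f"{spectrum_id} line {lineno}: {exc}") from exc
    if not peaks:
        logger.warning("%s: no fragment peaks, spectrum skipped", spectrum_id)
        return None
    return Spectrum(spectrum_id, mh, charge, peaks)


def read_dta(path: str | Path, precursor: str = "mh") -> Spectrum | None:
    """Parse a single-spectrum dta file; None when it has no fragment peaks."""
    path = Path(path)
    return _parse_dta_lines(
        path.read_text().splitlines(), path.stem, precursor
    )


def merge_dta(directory: str | Path, out_path: str | Path) -> int:
    """Concatenate all *.dta files into one blank-line-delimited text file.

    Records are ordered lexicographically by filename and tagged with a
    ``# <filename>`` comment header.  Returns the number of records written.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dta"))
    if not files:
        raise FileNotFoundError(f"no .dta files in {directory}")
    with Path(out_path).open("w") as out:
        for i, f in enumerate(files):
            if i:
                out.write("\n")
            out.write(f"# {f.name}\n")
            text = f.read_text()
            out.write("\n".join(ln for ln in text.splitlines() if ln.strip()))
            out.write("\n")
    return len(files)


def read_merged(path: str | Path, precursor: str = "mh") -> list[Spectrum]:
    """Parse a merged multi-spectrum file produced by :func:`merge_dta`."""
    spectra: list[Spectrum] = []
    block: list[str] = []
    block_id = ""

    def flush() -> None:
        nonlocal block, block_id
        if block:
            spec = _parse_dta_lines(block, block_id or f"spectrum{len(spectra)+1}", precursor)
            if spec is not None:
                spectra.append(spec)
        block, block_id = [], ""

    for line in Path(path).read_text().splitlines():
        if not line.strip():
            flush()
        elif line.startswith("#"):
            flush()
            block_id = Path(line[1:].strip()).stem
        else:
            block.append(line)
    flush()
    return spectra


# ---------------------------------------------------------------------------
# Processing stages
# ---------------------------------------------------------------------------

def filter_by_charge(
    spectra: Iterable[Spectrum], max_charge: int = 4
) -> list[Spectrum]:
    """Keep spectra with precursor charge <= max_charge."""
    kept, removed = [], 0
    for s in spectra:
        if s.charge <= max_charge:
            kept.append(s)
        else:
            removed += 1
    if removed:
        logger.info("charge filter removed %d spectra (z > %d)", removed, max_charge)
    return kept


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the base peak is exactly 100."""
    top = max(p.intensity for p in spectrum.peaks)
    if top <= 0:
        raise ValueError(f"{spectrum.spectrum_id}: all intensities are zero")
    scale = 100.0 / top
    peaks = [
        Peak(p.mz, 100.0 if p.intensity == top else p.intensity * scale)
        for p in spectrum.peaks
    ]
    return replace(spectrum, peaks=peaks, normalized=True)


def bin_denoise(spectrum: Spectrum, bin_size: int = 100) -> Spectrum:
    """Drop the less intense half of each m/z-ordered bin of peaks.

    Peaks are sorted by m/z and partitioned into consecutive bins of
    ``bin_size``; in each bin the floor(n/2) least intense peaks are
    removed (ties broken toward keeping the higher-m/z peak).
    """
    peaks = sorted(spectrum.peaks, key=lambda p: p.mz)
    kept: list[Peak] = []
    for start in range(0, len(peaks), bin_size):
        chunk = peaks[start:start + bin_size]
        n_drop = len(chunk) // 2
        if n_drop:
            ranked = sorted(chunk, key=lambda p: (p.intensity, p.mz))
            kept.extend(ranked[n_drop:])
        else:
            kept.extend(chunk)
    kept.sort(key=lambda p: p.mz)
    return replace(spectrum, peaks=kept)


def neutral_loss_check(
    spectrum: Spectrum,
    intensity_threshold: float,
    tol_base: float = 3.0,
    max_losses: int = 4,
) -> tuple[bool, list[Peak]]:
    """Select spectra showing an H3PO4 neutral-loss peak of the precursor.

    Candidate positions are ``precursor_mz - k * 97.976896 / z`` for
    k = 1..max_losses; the tolerance is ``tol_base / z``.  The spectrum
    passes when any candidate position holds a peak within tolerance whose
    intensity is >= the threshold.  A threshold of 0 still requires an
    actual matched peak.
    """
    if not 0 <= intensity_threshold <= 100:
        raise ValueError("intensity threshold must be in [0, 100]")
    z = spectrum.charge
    tol = tol_base / z
    mz0 = spectrum.precursor_mz
    candidates = [mz0 - k * chem.PHOSPHORIC_ACID / z for k in range(1, max_losses + 1)]
    matched = [
        p
        for p in spectrum.peaks
        if p.intensity >= intensity_threshold
        and any(abs(p.mz - c) <= tol for c in candidates)
    ]
    spectrum.nl_peaks = matched
    return bool(matched), matched


def process_spectrum(
    spectrum: Spectrum, bin_size: int = 100
) -> Spectrum:
    """normalize then bin_denoise, in the fixed pipeline order."""
    return bin_denoise(normalize(spectrum), bin_size)
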