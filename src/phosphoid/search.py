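"""Candidate generation and sigmoid-weighted fragment-match scoring.

For every database entry within precursor tolerance, all positional
phospho-isomers are expanded, a theoretical b/y spectrum with water,
ammonia and H3PO4 losses is generated, and the experimental peaks that
match any theoretical fragment are scored through a sigmoid weight of
their normalized intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from . import chem
from .peptide_db import CompositeDB, PeptideEntry
from .spectra import Peak, Spectrum


@dataclass(frozen=True)
class SiteConfig:
    """A specific placement of phospho groups on a peptide's S/T residues."""

    sequence: str
    phospho_positions: tuple[int, ...]  # 0-based indices, sorted

    def __post_init__(self) -> None:
        for pos in self.phospho_positions:
            if not 0 <= pos < len(self.sequence):
                raise ValueError(f"phospho position {pos} out of range")
            if self.sequence[pos] not in chem.PHOSPHO_RESIDUES:
                raise ValueError(
                    f"position {pos} ({self.sequence[pos]}) is not S/T"
                )

    @property
    def n_phospho(self) -> int:
        return len(self.phospho_positions)

    @property
    def modified_sequence(self) -> str:
        """Render with phospho residues in lower case, e.g. ``sCPEDCK``."""
        chars = list(self.sequence)
        for pos in self.phospho_positions:
            chars[pos] = chars[pos].lower()
        return "".join(chars)


@dataclass(frozen=True)
class Fragment:
    series: str  # "b" | "y"
    index: int
    loss: str    # "" | "H2O" | "NH3" | "H3PO4"
    charge: int
    mz: float


@dataclass
class TheoreticalSpectrum:
    config: SiteConfig
    fragments: list[Fragment]

    @property
    def mz_values(self) -> np.ndarray:
        return np.array([f.mz for f in self.fragments])


@dataclass
class Hit:
    """A scored candidate peptide-spectrum match."""

    config: SiteConfig
    score: float
    matched: int
    is_decoy: bool
    spectrum_id: str
    p_value: float | None = None

    @property
    def modified_sequence(self) -> str:
        return self.config.modified_sequence


@dataclass(frozen=True)
class SearchParams:
    precursor_tol: float = 7.0
    precursor_unit: str = "ppm"  # "Da" | "ppm"
    fragment_tol: float = 0.8    # Da
    fragment_charges: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.precursor_unit not in ("Da", "ppm"):
            raise ValueError("precursor_unit must be 'Da' or 'ppm'")

    def precursor_delta(self, precursor_mass: float) -> float:
        if self.precursor_unit == "Da":
            return self.precursor_tol
        return self.precursor_tol * precursor_mass / 1e6


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

def precursor_candidates(
    db: CompositeDB, spectrum: Spectrum, params: SearchParams
) -> list[PeptideEntry]:
    """Entries (target and decoy) within precursor mass tolerance."""
    mass = spectrum.precursor_neutral_mass
    return db.query_mass(mass, params.precursor_delta(mass))


def enumerate_site_configs(sequence: str, n_phospho: int) -> list[SiteConfig]:
    """All C(#S+T, n) phospho placements in lexicographic position order."""
    sites = [i for i, aa in enumerate(sequence) if aa in chem.PHOSPHO_RESIDUES]
    if n_phospho > len(sites):
        raise ValueError(
            f"{n_phospho} phospho groups cannot fit on {len(sites)} S/T sites"
        )
    return [
        SiteConfig(sequence, positions)
        for positions in combinations(sites, n_phospho)
    ]


# ---------------------------------------------------------------------------
# Theoretical spectrum
# ---------------------------------------------------------------------------

# Residue-content gating of neutral losses: water from S/T/E/D,
# ammonia from R/K/N/Q, phosphoric acid only from phosphorylated fragments.
_WATER_LOSS_RESIDUES = frozenset("STED")
_AMMONIA_LOSS_RESIDUES = frozenset("RKNQ")


def generate_theoretical(
    config: SiteConfig,
    params: SearchParams = SearchParams(),
    fixed_cam: bool = True,
) -> TheoreticalSpectrum:
    """b/y series with gated -H2O / -NH3 / -H3PO4 variants.

    Neutral fragment masses: b_i = residues 1..i (+mods), y_i = residues
    i+1..n (+mods) + H2O; ions add one proton per charge.
    """
    seq = config.sequence
    n = len(seq)
    phospho = set(config.phospho_positions)
    res = []
    for i, aa in enumerate(seq):
        m = chem.RESIDUE_MASS[aa]
        if fixed_cam and aa == "C":
            m += chem.CARBAMIDOMETHYL
        if i in phospho:
            m += chem.PHOSPHO
        res.append(m)
    prefix = np.cumsum(res)  # prefix[i] = mass of residues 0..i
    total = prefix[-1]

    fragments: list[Fragment] = []
    for i in range(1, n):
        # neutral masses of the b_i / y_{n-i} fragment pair
        b_neutral = prefix[i - 1]
        y_neutral = total - prefix[i - 1] + chem.WATER
        b_res = seq[:i]
        y_res = seq[i:]
        b_phos = any(p < i for p in phospho)
        y_phos = any(p >= i for p in phospho)
        for series, neutral, residues, has_phos, idx in (
            ("b", b_neutral, b_res, b_phos, i),
            ("y", y_neutral, y_res, y_phos, n - i),
        ):
            losses = [("", 0.0)]
            if set(residues) & _WATER_LOSS_RESIDUES:
                losses.append(("H2O", chem.WATER))
            if set(residues) & _AMMONIA_LOSS_RESIDUES:
                losses.append(("NH3", chem.AMMONIA))
            if has_phos:
                losses.append(("H3PO4", chem.PHOSPHORIC_ACID))
            for loss_name, loss_mass in losses:
                for z in params.fragment_charges:
                    mz = chem.mz_from_neutral(neutral - loss_mass, z)
                    if mz > 0:
                        fragments.append(Fragment(series, idx, loss_name, z, mz))
    return TheoreticalSpectrum(config, fragments)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def peak_score(intensity: float) -> float:
    """Sigmoid weight 2/(1+exp(-I)) - 1 of a matched peak's intensity."""
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    return 2.0 / (1.0 + math.exp(-intensity)) - 1.0


def score_match(
    spectrum: Spectrum,
    theoretical: TheoreticalSpectrum,
    params: SearchParams = SearchParams(),
) -> tuple[float, int, list[tuple[Peak, Fragment]]]:
    """Sum of sigmoid weights over matched experimental peaks.

    An experimental peak matches when it lies within the fragment tolerance
    of at least one theoretical fragment; each experimental peak is counted
    once, against its nearest fragment.
    """
    frags = theoretical.fragments
    if not frags or not spectrum.peaks:
        return 0.0, 0, []
    order = np.argsort([f.mz for f in frags])
    frag_mz = np.array([frags[i].mz for i in order])
    score = 0.0
    matched: list[tuple[Peak, Fragment]] = []
    for peak in spectrum.peaks:
        j = int(np.searchsorted(frag_mz, peak.mz))
        best, best_d = None, None
        for k in (j - 1, j):
            if 0 <= k < len(frag_mz):
                d = abs(frag_mz[k] - peak.mz)
                if best_d is None or d < best_d:
                    best, best_d = k, d
        if best is not None and best_d <= params.fragment_tol:
            score += peak_score(peak.intensity)
            matched.append((peak, frags[order[best]]))
    return score, len(matched), matched


def _hit_sort_key(hit: Hit) -> tuple:
    return (-hit.score, -hit.matched, hit.modified_sequence)


def search_spectrum(
    spectrum: Spectrum,
    db: CompositeDB,
    params: SearchParams = SearchParams(),
) -> tuple[list[Hit], list[Hit]]:
    """Score all site isomers of all precursor candidates.

    Returns (target hits, decoy hits), each sorted by descending score
    with deterministic tie-breaks.  Only candidates matching at least one
    experimental peak are recorded.
    """
    target: list[Hit] = []
    decoy: list[Hit] = []
    seen: set[tuple[str, bool]] = set()
    for entry in precursor_candidates(db, spectrum, params):
        for config in enumerate_site_configs(entry.sequence, entry.n_phospho):
            key = (config.modified_sequence, entry.is_decoy)
            if key in seen:
                continue
            seen.add(key)
            theo = generate_theoretical(config, params)
            score, m, _ = score_match(spectrum, theo, params)
            if m >= 1:
                hit = Hit(config, score, m, entry.is_decoy, spectrum.spectrum_id)
                (decoy if entry.is_decoy else target).append(hit)
    target.sort(key=_hit_sort_key)
    decoy.sort(key=_hit_sort_key)
    return target, decoy


def write_hits(path, hits: Iterable[Hit]) -> None:
    """Tab-separated hit list."""
    with open(path, "w") as fh:
        fh.write(
            "spectrum_id\tmodified_sequence\tn_phospho\tscore\tmatched\t"
            "is_decoy\tp_value\n"
        )
        for h in hits:
            p = "" if h.p_value is None else f"{h.p_value:.6g}"
            fh.write(
                f"{h.spectrum_id}\t{h.modified_sequence}\t{h.config.n_phospho}\t"
                f"{h.score:.6f}\t{h.matched}\t{int(h.is_decoy)}\t{p}\n"
            )
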