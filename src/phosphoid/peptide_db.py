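"""Target/decoy/composite peptide database construction.

Proteins are digested in silico (trypsin by default), modification states
are enumerated at the mass level (the number of phospho groups carried,
not their positions — positional isomers are expanded at search time),
and every entry gets a neutral monoisotopic mass.  Target and reversed
decoy entries are merged into a single mass-indexed composite database.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO

from . import chem

logger = logging.getLogger(__name__)

DECOY_PREFIX = "REV_"


@dataclass(frozen=True)
class Protein:
    """A validated protein record."""

    accession: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - chem.STANDARD_AA
        if bad:
            raise ValueError(
                f"{self.accession}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class DigestConfig:
    """In silico digestion parameters."""

    protease: str = "trypsin"
    max_missed_cleavages: int = 2
    min_length: int = 5
    max_length: int = 60

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid peptide length bounds")
        if self.protease not in PROTEASES:
            raise ValueError(
                f"unknown protease {self.protease!r}; "
                f"available: {sorted(PROTEASES)}"
            )


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable modification.

    Fixed modifications apply to every matching residue.  Variable
    modifications enumerate 0..min(#sites, max_per_peptide) copies.
    """

    residues: frozenset[str]
    mass_delta: float
    kind: str  # "fixed" | "variable"
    max_per_peptide: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "variable"):
            raise ValueError("kind must be 'fixed' or 'variable'")
        if self.kind == "variable" and self.max_per_peptide < 1:
            raise ValueError("variable modification needs max_per_peptide >= 1")


CAM_FIXED = ModificationSpec(frozenset("C"), chem.CARBAMIDOMETHYL, "fixed")
PHOSPHO_VARIABLE = ModificationSpec(
    frozenset(chem.PHOSPHO_RESIDUES), chem.PHOSPHO, "variable", max_per_peptide=4
)
DEFAULT_MODS = (CAM_FIXED, PHOSPHO_VARIABLE)


@dataclass(frozen=True)
class PeptideEntry:
    """A digested peptide with a modification-count state and its mass."""

    sequence: str
    n_phospho: int
    neutral_mass: float
    accession: str
    is_decoy: bool
    missed_cleavages: int


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def parse_fasta(path: str | Path) -> list[Protein]:
    """Read a protein FASTA file, rejecting records with non-standard residues.

    The accession is the header token before the first whitespace.  Records
    containing residues outside the 20 standard letters (e.g. B/X/Z) are
    dropped with a logged warning rather than raising.
    """
    proteins: list[Protein] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"record {record.id!r} has an empty sequence")
        bad = set(seq) - chem.STANDARD_AA
        if bad:
            logger.warning(
                "rejecting %s: non-standard residues %s", record.id, sorted(bad)
            )
            continue
        proteins.append(Protein(record.id, seq))
    if not proteins:
        raise ValueError(f"no usable protein records in {path}")
    return proteins


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def _trypsin_site(sequence: str, i: int) -> bool:
    # cleave C-terminal to K/R unless followed by P
    return sequence[i] in "KR" and (
        i + 1 >= len(sequence) or sequence[i + 1] != "P"
    )


def _chymotrypsin_low_site(sequence: str, i: int) -> bool:
    # low-specificity chymotrypsin: after F/L/M/W/Y unless followed by P
    return sequence[i] in "FLMWY" and (
        i + 1 >= len(sequence) or sequence[i + 1] != "P"
    )


PROTEASES: dict[str, Callable[[str, int], bool]] = {
    "trypsin": _trypsin_site,
    "chymotrypsin": _chymotrypsin_low_site,
}


def cleavage_sites(sequence: str, protease: str = "trypsin") -> list[int]:
    """Positions i such that the bond between i and i+1 is cleaved."""
    rule = PROTEASES[protease]
    return [i for i in range(len(sequence) - 1) if rule(sequence, i)]


def digest(
    sequence: str, config: DigestConfig = DigestConfig()
) -> list[tuple[str, int]]:
    """Fully specific digestion with missed cleavages.

    Returns ``(peptide, missed_cleavage_count)`` pairs for every contiguous
    stretch delimited by cleavage boundaries spanning at most
    ``max_missed_cleavages`` internal uncleaved sites, subject to the
    configured length guards.
    """
    sites = cleavage_sites(sequence, config.protease)
    # boundary positions in string-slice coordinates
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides: list[tuple[str, int]] = []
    for a in range(len(bounds) - 1):
        for mc in range(config.max_missed_cleavages + 1):
            b = a + 1 + mc
            if b >= len(bounds):
                break
            pep = sequence[bounds[a]:bounds[b]]
            if config.min_length <= len(pep) <= config.max_length:
                peptides.append((pep, mc))
    return peptides


# ---------------------------------------------------------------------------
# Modification enumeration and mass computation
# ---------------------------------------------------------------------------

def compute_mass(
    sequence: str,
    n_phospho: int = 0,
    fixed_mods: Sequence[ModificationSpec] = (CAM_FIXED,),
) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    mass = chem.residue_sum(sequence) + chem.WATER + chem.PHOSPHO * n_phospho
    for mod in fixed_mods:
        if mod.kind != "fixed":
            raise ValueError("compute_mass only applies fixed modifications")
        mass += mod.mass_delta * sum(sequence.count(r) for r in mod.residues)
    return mass


def enumerate_mod_states(
    peptide: str,
    missed_cleavages: int,
    accession: str,
    is_decoy: bool,
    mod_specs: Sequence[ModificationSpec] = DEFAULT_MODS,
) -> list[PeptideEntry]:
    """One entry per variable-modification count 0..min(#sites, max)."""
    fixed = tuple(m for m in mod_specs if m.kind == "fixed")
    variable = [m for m in mod_specs if m.kind == "variable"]
    if len(variable) > 1:
        raise ValueError("only one variable modification is supported")
    entries: list[PeptideEntry] = []
    if variable:
        var = variable[0]
        n_sites = sum(peptide.count(r) for r in var.residues)
        n_max = min(n_sites, var.max_per_peptide)
    else:
        n_max = 0
    for n in range(n_max + 1):
        entries.append(
            PeptideEntry(
                sequence=peptide,
                n_phospho=n,
                neutral_mass=compute_mass(peptide, n, fixed),
                accession=accession,
                is_decoy=is_decoy,
                missed_cleavages=missed_cleavages,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Decoy and composite database
# ---------------------------------------------------------------------------

def build_decoy(proteins: Iterable[Protein]) -> list[Protein]:
    """One reversed decoy per target protein, accession prefixed."""
    return [
        Protein(DECOY_PREFIX + p.accession, p.sequence[::-1], is_decoy=True)
        for p in proteins
    ]


@dataclass
class CompositeDB:
    """Mass-sorted collection of target and decoy peptide entries.

    ``K`` is the number of TARGET entries only — the Bonferroni divisor.
    """

    entries: list[PeptideEntry]
    config: DigestConfig = field(default_factory=DigestConfig)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.neutral_mass)
        self._masses = [e.neutral_mass for e in self.entries]

    @property
    def K(self) -> int:
        return sum(1 for e in self.entries if not e.is_decoy)

    def __len__(self) -> int:
        return len(self.entries)

    def query_mass(self, mass: float, delta: float) -> list[PeptideEntry]:
        """All entries with |neutral_mass - mass| <= delta (inclusive)."""
        lo = bisect_left(self._masses, mass - delta)
        hi = bisect_right(self._masses, mass + delta)
        return self.entries[lo:hi]

    # -- persistence (plain text) -------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(
                "accession\tsequence\tn_phospho\tneutral_mass\t"
                "missed_cleavages\tis_decoy\n"
            )
            for e in self.entries:
                fh.write(
                    f"{e.accession}\t{e.sequence}\t{e.n_phospho}\t"
                    f"{e.neutral_mass:.6f}\t{e.missed_cleavages}\t"
                    f"{int(e.is_decoy)}\n"
                )
        meta = {
            "K": self.K,
            "n_entries": len(self.entries),
            "config": {
                "protease": self.config.protease,
                "max_missed_cleavages": self.config.max_missed_cleavages,
                "min_length": self.config.min_length,
                "max_length": self.config.max_length,
            },
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CompositeDB":
        path = Path(path)
        entries: list[PeptideEntry] = []
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("accession\t"):
                raise ValueError(f"{path}: not a composite database file")
            for line in fh:
                acc, seq, n_p, mass, mc, dec = line.rstrip("\n").split("\t")
                entries.append(
                    PeptideEntry(seq, int(n_p), float(mass), acc, bool(int(dec)), int(mc))
                )
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        config = DigestConfig()
        if meta_path.exists():
            cfg = json.loads(meta_path.read_text())["config"]
            config = DigestConfig(**cfg)
        return cls(entries, config)


def build_composite(
    targets: Iterable[Protein],
    decoys: Iterable[Protein],
    config: DigestConfig = DigestConfig(),
    mod_specs: Sequence[ModificationSpec] = DEFAULT_MODS,
) -> CompositeDB:
    """Digest targets and decoys, enumerate modification states, merge."""
    entries: list[PeptideEntry] = []
    seen: set[tuple[str, int, bool]] = set()
    for protein in list(targets) + list(decoys):
        for pep, mc in digest(protein.sequence, config):
            key = (pep, mc, protein.is_decoy)
            if key in seen:
                continue
            seen.add(key)
            entries.extend(
                enumerate_mod_states(
                    pep, mc, protein.accession, protein.is_decoy, mod_specs
                )
            )
    return CompositeDB(entries, config)
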