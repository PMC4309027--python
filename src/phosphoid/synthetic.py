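"""Ground-truthed synthetic CID spectra for end-to-end testing.

Spectra are written as standard dta files: a sampled fraction of the
theoretical b/y fragments with jittered m/z, uniform noise peaks, and —
for phosphopeptides — a dominant precursor H3PO4 neutral-loss peak, the
structure the prescreening and scoring stages assume.  A fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import chem
from .peptide_db import DigestConfig, Protein, digest
from .search import SiteConfig, SearchParams, generate_theoretical
from .spectra import Peak, Spectrum

# Twenty invented protein sequences; enough tryptic S/T peptides for the
# whole pipeline to be exercised without any external download.
BUNDLED_PROTEINS: tuple[tuple[str, str], ...] = (
    ("SYN01", "KRCRSQTTGNEWRGSNNFCCGGTSASLISIQRTIGKSTQRNTTHDSEMDLWIYCPTRKREFMQQSNTSCETSFASMDLEGWIHTV"),
    ("SYN02", "TTSTSDSMFSAGVVLKMHWPNQHVEFTYSLSMMISSETECPFSENWSWHCDLRCVHTHKTEPDQVNSTKSCWNG"),
    ("SYN03", "SNINPLYLIYTENHSRSNSTKWLADEESKRMEGQNFGEGDLHSDAYIVTGTHWLKDIRKPKGLYKAKLTQFADSTGHSMCIEDRYVTNKSKEKRSNRCSSD"),
    ("SYN04", "LATVWVNSSFDEDGEICTGTTNAFQCKTREFSCATQRTWTPMGCPTIRGWSYQGTTKRWWHFRFAHAKFGPARVSSTASTVEAHHCQLPWIKRTCGQHLSQTNVWKT"),
    ("SYN05", "TTCTHLSRGINFIIRMTDIWWSTSCADQPSYSCLIWDCFCIDTDRSSFCPREDARFCCGRGQKTVETGPRQSNCKDYHHPSPGCLEPLHTNSCTKMDFFSS"),
    ("SYN06", "KVSKMRIDITWEFNGTNKYRQVDTSKTATATATDKETHKRTSTYTVSNSIRCIVSPKSSMTRYYHTCSRYKGIGRGLPMVTDKEFSLGREY"),
    ("SYN07", "LSYEVTTLSKSCTNCDYTFWSTDHESVKKRHGGLKAQATYQDDQAVSGLTKSSPVPCELPQIYIANHRISRSRKESTEHSSIYPYQYMVMLETNATLLYCFRMFWCIRMY"),
    ("SYN08", "ALRYKKHYSNVTKEQQKCSTFEQVAEGFVEMNSMDDRGVNRTIDIIYSYQDTVTEQIGAKCVDSMIINSTTFGTKQTDKGSWIALAQTKMLDCYNSSSESEHYGDTHSSRWETVDMSQPY"),
    ("SYN09", "HCVMVTTYYLRSDIDGNKNITSTVLIRCPYTNVAQPLYMATMNCSHSETVTDISQAFPSTKGHNRNSYQYRHTSSYIRQKSDSVLYR"),
    ("SYN10", "FYQATRDWTSTTDQAHYITPRVWKSTNGALAMWRRTWECEKSTQTPWIEQAQAWWEGLRQSYPWVFWDMTSIFTTLCSQMESNYCHSCMAWT"),
    ("SYN11", "DFTQGVKFFTRVLDSADYWLEATRKLDDRIKYTTSMEREGIKDEVIHNSSSETHRHYISGPRTYFGHPQLSGWSSPWKATSTITRFICVMSTNTVKYSEKSESIQSTDSITTSKVPCTFV"),
    ("SYN12", "FASECRIKQNVTTMHAFATTTSCRGTLCRFHYQTIAKFWETMLTQWSLSDVLEMPPYMLETHWRWKRRDSATRSKDQSSAQWFHYN"),
    ("SYN13", "QKMNKNSTTDRQYMDQFIDSSRSSSRPYKSQCQLEHPMEGVRYFHTPTILFHASWDTEWSDWNSRTDKWVSSTISIGSCTTLRSESA"),
    ("SYN14", "MFGRNTAVSSECGKWYFLYILCGKGIEHPYTFDNESMYRINLTYMFLRVIFNDPFGSSRCWRQLMQALSTFPESNGLYSCFTTKYDSMDHLMRRAEFHSHRSFKGQSDTNSSCPIQTT"),
    ("SYN15", "TDQMDGHETNRSIRHLFDGMYTPTRYTQAWMKQSHLGSHSVAFTHTSAKDCRIYSETSNDYK"),
    ("SYN16", "VVCGEIASTKANGYYAWHYTVTPFYRLPRSGTSWAWFPAEMQLTSRTFKAKSIAYWTMMVTSHTRKTCYFKWSDASANSQIRSHFTMLMTHSCKGLSVYIL"),
    ("SYN17", "VLPIVFYSNYKPSWESISDNHSEVEFTMSFHIDPLSPRRSQQSALKTRYMAMSKRTEAAYHHLMLDKAD"),
    ("SYN18", "SAITCGTWCLKENAKTYRKMSHCKPEWANSLSWGYSPLSPLTRPPWSDALCNRSIFACVRIAWHWRYGEHVCTSSTN"),
    ("SYN19", "YVLGTFMQTCAFRHRVDPNFWIKTGWTSKARWWLISCAKSHHHSKSAEMITVPFMATLRHMSSILTHLGTVCSGVSGKFAAKGANYSMYMWTSTLYWIQQQSK"),
    ("SYN20", "YYAIDSQRCMFKLTRWKRSSTTVGKLGFDVGFEPWCSAPWWTLTVTFFQYIYSFNYSNRMPWEPNWKSKLESPIDSVSESSTTAKTPKQVLAREHCMFSKKQL"),
)


def bundled_proteins() -> list[Protein]:
    return [Protein(acc, seq) for acc, seq in BUNDLED_PROTEINS]


def write_bundled_fasta(path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for acc, seq in BUNDLED_PROTEINS:
            fh.write(f">{acc} synthetic\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generative model."""

    charges: tuple[int, ...] = (2, 3)
    coverage: float = 0.85            # fraction of b/y fragments emitted
    fragment_intensity: tuple[float, float] = (20.0, 80.0)
    nl_intensity: float = 100.0       # dominant by default
    n_noise: int = 20
    noise_intensity: tuple[float, float] = (1.0, 15.0)
    mz_jitter: float = 0.02           # gaussian s.d. in Da
    noise_mz_range: tuple[float, float] = (100.0, 1800.0)

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")


def simulate_spectrum(
    site_config: SiteConfig,
    charge: int,
    sim: SimConfig,
    rng: np.random.Generator,
    spectrum_id: str = "sim",
) -> Spectrum:
    """One spectrum for a peptide (phospho or not) under the model above."""
    theo = generate_theoretical(
        site_config, SearchParams(fragment_charges=(1,))
    )
    # signal peaks: the plain b/y series only (losses are left to noise)
    backbone = [f for f in theo.fragments if f.loss == ""]
    n_keep = max(1, int(round(sim.coverage * len(backbone))))
    idx = rng.choice(len(backbone), size=n_keep, replace=False)
    lo, hi = sim.fragment_intensity
    peaks = [
        Peak(
            max(1e-6, backbone[i].mz + rng.normal(0.0, sim.mz_jitter)),
            rng.uniform(lo, hi),
        )
        for i in sorted(idx)
    ]
    neutral = chem.peptide_mass(site_config.sequence, site_config.n_phospho)
    precursor_mh = neutral + chem.PROTON
    precursor_mz = chem.mz_from_neutral(neutral, charge)
    if site_config.n_phospho > 0 and sim.nl_intensity > 0:
        nl_mz = precursor_mz - chem.PHOSPHORIC_ACID / charge
        peaks.append(
            Peak(nl_mz + rng.normal(0.0, sim.mz_jitter), sim.nl_intensity)
        )
    nlo, nhi = sim.noise_intensity
    mlo, mhi = sim.noise_mz_range
    for _ in range(sim.n_noise):
        peaks.append(Peak(rng.uniform(mlo, mhi), rng.uniform(nlo, nhi)))
    peaks.sort(key=lambda p: p.mz)
    return Spectrum(spectrum_id, precursor_mh, charge, peaks)


def write_dta(spectrum: Spectrum, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"{spectrum.precursor_mh:.6f} {spectrum.charge}\n")
        for p in spectrum.peaks:
            fh.write(f"{p.mz:.6f} {p.intensity:.4f}\n")


def _peptide_pool(min_st: int = 0) -> list[str]:
    cfg = DigestConfig(min_length=7, max_length=25, max_missed_cleavages=0)
    pool: set[str] = set()
    for protein in bundled_proteins():
        for pep, _mc in digest(protein.sequence, cfg):
            n_st = sum(pep.count(r) for r in chem.PHOSPHO_RESIDUES)
            if n_st >= min_st:
                pool.add(pep)
    return sorted(pool)


def simulate_dataset(
    n_phospho: int,
    n_nonphospho: int,
    sim: SimConfig,
    out_dir: str | Path,
    seed: int = 0,
) -> Path:
    """Write a mixture of phospho/non-phospho dta files plus a truth table.

    Non-phospho spectra carry no planted neutral-loss peak (noise may
    still land near a candidate position).  Returns the truth-table path;
    its rows are ``spectrum_id <TAB> modified_sequence`` with an empty
    sequence column for non-phospho spectra.
    """
    if n_phospho < 0 or n_nonphospho < 0:
        raise ValueError("counts must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    phospho_pool = _peptide_pool(min_st=1)
    plain_pool = _peptide_pool(min_st=0)
    truth_path = out_dir / "truth.tsv"
    n_total = n_phospho + n_nonphospho
    width = max(4, len(str(n_total)))
    with truth_path.open("w") as truth:
        truth.write("spectrum_id\tmodified_sequence\n")
        for i in range(n_total):
            spectrum_id = f"sim{i:0{width}d}"
            is_phos = i < n_phospho
            if is_phos:
                pep = phospho_pool[rng.integers(len(phospho_pool))]
                sites = [
                    j for j, aa in enumerate(pep) if aa in chem.PHOSPHO_RESIDUES
                ]
                n_p = int(rng.integers(1, min(2, len(sites)) + 1))
                positions = tuple(
                    sorted(rng.choice(sites, size=n_p, replace=False).tolist())
                )
                config = SiteConfig(pep, positions)
            else:
                pep = plain_pool[rng.integers(len(plain_pool))]
                config = SiteConfig(pep, ())
            z = int(sim.charges[rng.integers(len(sim.charges))])
            spectrum = simulate_spectrum(config, z, sim, rng, spectrum_id)
            write_dta(spectrum, out_dir / f"{spectrum_id}.dta")
            truth.write(
                f"{spectrum_id}\t{config.modified_sequence if is_phos else ''}\n"
            )
    return truth_path


def read_truth(path: str | Path) -> dict[str, str]:
    """Truth table as spectrum_id -> modified sequence ('' = non-phospho)."""
    truth: dict[str, str] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("spectrum_id"):
            raise ValueError(f"{path}: not a truth table")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            truth[parts[0]] = parts[1] if len(parts) > 1 else ""
    return truth
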