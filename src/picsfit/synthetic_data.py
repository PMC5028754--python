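"""Synthetic inputs for the whole pipeline.

No raw MS or calorimetry data accompany the screen this package models, so
every input is emulated here: a random proteome, a trypsin-style
proteome-derived peptide library, in-silico cleavage of that library by a
protease with a planted subsite specificity (plus MS-like identification
noise), and forward-simulated binding isotherms.  All generators are
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .itc import (
    InjectionProtocol,
    OneSiteParams,
    Titration,
    TwoSiteParams,
    simulate_titration,
)
from .pics_filter import AA_ALPHABET, PeptideID, RunSet

__all__ = [
    "Proteome",
    "DigestRule",
    "LibraryPeptide",
    "ProteaseSpec",
    "NoiseSettings",
    "InjectionProtocol",
    "generate_proteome",
    "digest_proteome",
    "simulate_pics_runs",
    "simulate_isotherm",
    "TRYPSIN",
]

SUBSITE_LABELS = ("P5", "P4", "P3", "P2", "P1", "P1p", "P2p", "P3p", "P4p", "P5p")


@dataclass(frozen=True)
class Proteome:
    """A set of protein sequences standing in for a search database."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("protein ids must be unique")
        for pid, seq in self.entries:
            if not seq:
                raise ValueError(f"empty sequence for {pid!r}")
            bad = set(seq) - set(AA_ALPHABET)
            if bad:
                raise ValueError(f"non-canonical residues in {pid!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DigestRule:
    """Site-specific digestion rule for library construction.

    Cleaves after any residue in `cleave_after` unless the following residue
    is in `blocked_by_next`; fragments outside [min_len, max_len] are then
    discarded.
    """

    name: str
    cleave_after: frozenset
    blocked_by_next: frozenset
    min_len: int = 1
    max_len: int = 10**9

    def __post_init__(self) -> None:
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))
        object.__setattr__(self, "blocked_by_next", frozenset(self.blocked_by_next))
        if not self.cleave_after <= set(AA_ALPHABET):
            raise ValueError("cleave_after must be canonical residues")
        if not self.blocked_by_next <= set(AA_ALPHABET):
            raise ValueError("blocked_by_next must be canonical residues")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")


#: default library protease: cleave after K/R, not before P, MS-friendly lengths
TRYPSIN = DigestRule(
    name="trypsin", cleave_after=frozenset("KR"), blocked_by_next=frozenset("P"),
    min_len=5, max_len=40,
)


@dataclass(frozen=True)
class LibraryPeptide:
    """A library peptide with parent-protein coordinates (1-based inclusive)."""

    sequence: str
    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")


@dataclass(frozen=True)
class ProteaseSpec:
    """Planted substrate specificity of the simulated test protease.

    `preference` maps subsite labels (P5..P1, P1p..P5p) to per-residue
    weights; omitted subsites are uniform.  A site's cleavage probability is
    `efficiency` times the product over subsites of weight/max-weight, so a
    window matching every preferred residue is cleaved with probability
    `efficiency` and a strict (one-hot) motif forbids everything else.
    Subsites that fall outside the peptide contribute a neutral factor.
    """

    preference: dict = field(default_factory=dict)
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        for label, weights in self.preference.items():
            if label not in SUBSITE_LABELS:
                raise ValueError(f"unknown subsite {label!r}")
            if any(w < 0 for w in weights.values()):
                raise ValueError("weights must be non-negative")
            if not weights or max(weights.values()) <= 0:
                raise ValueError(f"subsite {label!r} needs a positive weight")

    def site_probability(self, peptide: str, bond: int) -> float:
        """Cleavage probability of the bond after residue `bond` (1-based)."""
        p = self.efficiency
        for k, label in enumerate(SUBSITE_LABELS):
            weights = self.preference.get(label)
            if not weights:
                continue
            idx = bond - 5 + k  # 0-based residue index at this subsite
            if not 0 <= idx < len(peptide):
                continue
            wmax = max(weights.values())
            p *= weights.get(peptide[idx], 0.0) / wmax
            if p == 0.0:
                return 0.0
        return p


@dataclass(frozen=True)
class NoiseSettings:
    """MS-like identification noise for the simulated screen.

    Background peptides (uncleaved library members plus a fraction of
    shuffled decoys) are drawn once and copied into the test, inactive and
    mock runs with identical flags and confidences, so control subtraction
    is meaningful.  Confidences are percentages.
    """

    n_background: int = 0
    background_biotin_prob: float = 0.3
    decoy_fraction: float = 0.1
    product_confidence: tuple[float, float] = (85.0, 100.0)
    background_confidence: tuple[float, float] = (0.0, 100.0)
    library_run_fraction: float = 1.0
    min_product_len: int = 1

    def __post_init__(self) -> None:
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        for p in (self.background_biotin_prob, self.decoy_fraction, self.library_run_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.product_confidence, self.background_confidence):
            if not 0.0 <= lo <= hi <= 100.0:
                raise ValueError("confidence ranges must lie in [0, 100]")


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    aa_frequencies=None,
    seed: int = 0,
) -> Proteome:
    """Random proteome with i.i.d. residues.

    `aa_frequencies` is a 20-vector over the alphabet ACDEFGHIKLMNPQRSTVWY
    (uniform when omitted); lengths are uniform over `length_range`
    (inclusive).  Deterministic for a fixed seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("need 1 <= min length <= max length")
    if aa_frequencies is None:
        freqs = np.full(20, 1.0 / 20.0)
    else:
        freqs = np.asarray(aa_frequencies, dtype=float)
        if freqs.shape != (20,) or np.any(freqs < 0):
            raise ValueError("aa_frequencies must be 20 non-negative values")
        total = freqs.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("aa_frequencies must sum to 1")
        freqs = freqs / total
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_ALPHABET))
    entries = []
    width = len(str(n_proteins))
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=freqs))
        entries.append((f"SYN{i + 1:0{width}d}", seq))
    return Proteome(entries=tuple(entries))


def digest_proteome(proteome: Proteome, rule: DigestRule) -> list[LibraryPeptide]:
    """Fragment every protein by the digestion rule, then length-filter.

    Before filtering, the fragments of each protein tile it exactly.
    """
    peptides: list[LibraryPeptide] = []
    for pid, seq in proteome.entries:
        start = 0  # 0-based fragment start
        for i, res in enumerate(seq):
            last = i == len(seq) - 1
            if last or (res in rule.cleave_after and seq[i + 1] not in rule.blocked_by_next):
                frag = seq[start:i + 1]
                if rule.min_len <= len(frag) <= rule.max_len:
                    peptides.append(
                        LibraryPeptide(frag, pid, start=start + 1, end=i + 1)
                    )
                start = i + 1
    return peptides


def _background_ids(
    library: list[LibraryPeptide], noise: NoiseSettings, rng: np.random.Generator
) -> list[tuple[str, bool, float]]:
    """Sample the shared background (sequence, biotin, confidence) triples."""
    out = []
    if noise.n_background == 0 or not library:
        return out
    n_decoy = int(round(noise.n_background * noise.decoy_fraction))
    idx = rng.integers(0, len(library), size=noise.n_background)
    lo, hi = noise.background_confidence
    for k, i in enumerate(idx):
        seq = library[int(i)].sequence
        if k < n_decoy and len(seq) > 1:
            perm = rng.permutation(len(seq))
            seq = "".join(seq[j] for j in perm)
        biotin = bool(rng.random() < noise.background_biotin_prob)
        conf = float(rng.uniform(lo, hi))
        out.append((seq, biotin, conf))
    return out


def simulate_pics_runs(
    library: list[LibraryPeptide],
    protease: ProteaseSpec,
    noise: NoiseSettings | None = None,
    seed: int = 0,
) -> RunSet:
    """Simulate the four identification lists of one screen.

    Each internal bond of each library peptide is cleaved independently with
    probability efficiency x normalized motif match; cleavage emits the
    prime-side fragment as a biotin-flagged high-confidence identification
    in the test run.  Background peptides are shared verbatim across the
    test and both control runs; the library run re-identifies a fraction of
    the unprocessed library.  With efficiency 0 the test run equals the mock
    run exactly.
    """
    if not library:
        raise ValueError("library must be non-empty")
    noise = noise or NoiseSettings()
    rng = np.random.default_rng(seed)

    # cleavage products (test run only)
    products: list[PeptideID] = []
    clo, chi = noise.product_confidence
    for pep in library:
        for bond in range(1, len(pep.sequence)):
            p = protease.site_probability(pep.sequence, bond)
            if p > 0.0 and rng.random() < p:
                frag = pep.sequence[bond:]
                if len(frag) < noise.min_product_len:
                    continue
                products.append(
                    PeptideID(frag, nterm_biotin=True,
                              confidence=float(rng.uniform(clo, chi)),
                              run_label="test")
                )

    background = _background_ids(library, noise, rng)

    def as_ids(label: str) -> list[PeptideID]:
        return [PeptideID(s, b, c, run_label=label) for s, b, c in background]

    test = products + as_ids("test")
    inactive = as_ids("inactive")
    mock = as_ids("mock")

    lib_run: list[PeptideID] = []
    lo, hi = noise.background_confidence
    for pep in library:
        if rng.random() < noise.library_run_fraction:
            lib_run.append(
                PeptideID(pep.sequence, nterm_biotin=False,
                          confidence=float(rng.uniform(lo, hi)),
                          run_label="library")
            )
    return RunSet(test=test, inactive=inactive, mock=mock, library=lib_run)


def simulate_isotherm(
    protocol: InjectionProtocol,
    params: OneSiteParams | TwoSiteParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Titration:
    """Forward-simulate an ITC run (gaussian noise on normalized heats)."""
    return simulate_titration(protocol, params, noise_sd=noise_sd, seed=seed)
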