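"""The 54-feature representation of a hairpin candidate.

Feature groups, in canonical column order:

1. 32 triplet elements — for every interior position, the pairing states of
   the three residues centred on it ('(' for paired in either direction, '.'
   for unpaired) keyed by the middle nucleotide; counts normalised by the
   number of windows (L-2) so the block sums to 1.
2. 4 sequential features — %G+C, sequence length, hairpin length (nt span of
   the main stem-loop) and loop length (largest terminal loop).
3. 8 thermodynamic features — dP = n_bp/L, dG = MFE/L, their
   dinucleotide-shuffle z-scores zP and zG, and the four MFE indices
   MFEI_1 = dG / %G+C, MFEI_2 = dG / n_stems, MFEI_3 = dG / n_loops,
   MFEI_4 = MFE / n_bp.
4. 8 base-pair features — |A-U|/L, |G-C|/L, |G-U|/L, the per-stem variants
   %(X-Y)/stems (with %(X-Y) = 100*|X-Y|/L), ConsecBP (longest stacked run)
   and Avg_BP_Stem = n_bp / n_stems.
5. 2 ensemble features — Frequency of the MFE structure and the base-pair
   Diversity of the Boltzmann ensemble.

Any feature whose denominator is zero on a given record (no stems, no loops,
no pairs, zero shuffle spread) is set to 0 and flagged; unpaired random
fragments routinely hit these cases and must still be classifiable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DataError
from .folding import FoldConfig, SecondaryStructure, ensemble_stats, fold_mfe
from .io import RnaSequence
from .shuffle import dinucleotide_shuffle
from .structure import StructureStats, analyze_structure

logger = logging.getLogger(__name__)

TRIPLET_PATTERNS = ("(((", "((.", "(.(", ".((", "(..", ".(.", "..(", "...")
NUCLEOTIDES = "ACGU"

#: The 32 triplet feature names, e.g. "A(((", "G..(".
TRIPLET_NAMES = tuple(f"{nt}{pat}" for nt in NUCLEOTIDES for pat in TRIPLET_PATTERNS)

SEQUENTIAL_NAMES = ("%G+C", "sequence length", "hairpin length", "loop length")
THERMODYNAMIC_NAMES = ("dP", "dG", "zP", "zG", "MFEI_1", "MFEI_2", "MFEI_3", "MFEI_4")
BASEPAIR_NAMES = (
    "|A-U|/L",
    "|G-C|/L",
    "|G-U|/L",
    "%(A-U)/stems",
    "%(G-C)/stems",
    "%(G-U)/stems",
    "ConsecBP",
    "Avg_BP_Stem",
)
ENSEMBLE_NAMES = ("Frequency", "Diversity")

#: Canonical order of all 54 features.
FEATURE_NAMES: tuple[str, ...] = (
    TRIPLET_NAMES + SEQUENTIAL_NAMES + THERMODYNAMIC_NAMES + BASEPAIR_NAMES + ENSEMBLE_NAMES
)
assert len(FEATURE_NAMES) == 54

_CANONICAL_PAIRS = {
    frozenset("AU"): "AU",
    frozenset("GC"): "GC",
    frozenset("GU"): "GU",
}


@dataclass
class FeatureVector:
    """54 named feature values plus degenerate-denominator flags."""

    values: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (54,):
            raise ValueError(f"expected 54 features, got shape {self.values.shape}")

    def as_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES), name=name)

    def __getitem__(self, feature: str) -> float:
        return float(self.values[FEATURE_NAMES.index(feature)])


def triplet_features(seq: RnaSequence, structure: SecondaryStructure) -> np.ndarray:
    """Frequencies of the 32 middle-nucleotide x pairing-pattern triplets.

    Both bracket directions count as paired ('(').  Sequences shorter than 3
    nt have no windows; a zero vector is returned with a warning.
    """
    L = len(seq)
    if len(structure.dotbracket) != L:
        raise ValueError("structure length does not match sequence length")
    counts = np.zeros(32)
    if L < 3:
        logger.warning("record %r: L < 3, triplet features undefined (zeros)", seq.id)
        return counts
    states = "".join("(" if p else "." for p in structure.pairs[1:])
    index = {name: i for i, name in enumerate(TRIPLET_NAMES)}
    for m in range(1, L - 1):
        key = seq.residues[m] + states[m - 1 : m + 2]
        counts[index[key]] += 1
    return counts / (L - 2)


def sequential_features(seq: RnaSequence, stats: StructureStats) -> dict:
    gc = 100.0 * sum(c in "GC" for c in seq.residues) / len(seq)
    return {
        "%G+C": gc,
        "sequence length": float(len(seq)),
        "hairpin length": float(stats.hairpin_span),
        "loop length": float(stats.terminal_loop_len),
    }


def _safe_ratio(num: float, den: float, name: str, flags: dict) -> float:
    if den == 0:
        flags[name] = "zero_denominator"
        return 0.0
    return num / den


def thermodynamic_features(
    seq: RnaSequence,
    structure: SecondaryStructure,
    stats: StructureStats,
    shuffles: int = 1000,
    seed: int = 0,
    config: FoldConfig | None = None,
    flags: dict | None = None,
) -> dict:
    """dP, dG, shuffle z-scores and the four MFE indices.

    z-scores fold ``shuffles`` dinucleotide-preserving shuffles of the
    sequence with the *same* fold configuration and standardise the observed
    dP and dG against that null; an all-identical null (sd = 0, e.g. a
    homopolymer) yields z = 0, flagged.
    """
    if shuffles < 2:
        raise ValueError("shuffles must be >= 2")
    config = config or FoldConfig()
    flags = flags if flags is not None else {}
    L = len(seq)
    gc = 100.0 * sum(c in "GC" for c in seq.residues) / L
    n_bp = stats.n_bp
    dP = n_bp / L
    dG = structure.mfe / L

    rng = np.random.default_rng(seed)
    null_dP = np.empty(shuffles)
    null_dG = np.empty(shuffles)
    for t in range(shuffles):
        shuffled = RnaSequence(id=f"{seq.id}|shuffle{t}",
                               residues=dinucleotide_shuffle(seq.residues, rng))
        fold = fold_mfe(shuffled, config)
        null_dP[t] = fold.n_bp / L
        null_dG[t] = fold.mfe / L

    def zscore(x: float, null: np.ndarray, name: str) -> float:
        sd = float(null.std(ddof=1))
        if sd == 0.0:
            flags[name] = "zero_shuffle_sd"
            return 0.0
        return (x - float(null.mean())) / sd

    return {
        "dP": dP,
        "dG": dG,
        "zP": zscore(dP, null_dP, "zP"),
        "zG": zscore(dG, null_dG, "zG"),
        "MFEI_1": _safe_ratio(dG, gc, "MFEI_1", flags),
        "MFEI_2": _safe_ratio(dG, stats.n_stems, "MFEI_2", flags),
        "MFEI_3": _safe_ratio(dG, stats.n_loops, "MFEI_3", flags),
        "MFEI_4": _safe_ratio(structure.mfe, n_bp, "MFEI_4", flags),
    }


def basepair_features(
    seq: RnaSequence,
    structure: SecondaryStructure,
    stats: StructureStats,
    flags: dict | None = None,
) -> dict:
    """Pair-type tallies and stem-normalised variants.

    Raises :class:`DataError` if a paired position holds a non-canonical
    nucleotide combination (possible for externally supplied structures).
    """
    flags = flags if flags is not None else {}
    L = len(seq)
    counts = {"AU": 0, "GC": 0, "GU": 0}
    for i in range(1, L + 1):
        j = structure.pairs[i]
        if j > i:
            key = _CANONICAL_PAIRS.get(
                frozenset((seq.residues[i - 1], seq.residues[j - 1]))
            )
            if key is None:
                raise DataError(
                    f"record {seq.id!r}: non-canonical pair "
                    f"{seq.residues[i - 1]}-{seq.residues[j - 1]} at positions {i}-{j}"
                )
            counts[key] += 1
    n_stems = stats.n_stems
    out = {
        "|A-U|/L": counts["AU"] / L,
        "|G-C|/L": counts["GC"] / L,
        "|G-U|/L": counts["GU"] / L,
    }
    for xy, name in (("AU", "%(A-U)/stems"), ("GC", "%(G-C)/stems"), ("GU", "%(G-U)/stems")):
        out[name] = _safe_ratio(100.0 * counts[xy] / L, n_stems, name, flags)
    out["ConsecBP"] = float(stats.consec_bp)
    out["Avg_BP_Stem"] = _safe_ratio(stats.n_bp, n_stems, "Avg_BP_Stem", flags)
    return out


def extract_all(
    seq: RnaSequence,
    config: FoldConfig | None = None,
    shuffles: int = 1000,
    seed: int = 0,
    structure: SecondaryStructure | None = None,
) -> FeatureVector:
    """Fold (unless a structure is supplied) and compute all 54 features."""
    if len(seq) < 3:
        raise DataError(f"record {seq.id!r}: sequences shorter than 3 nt have no features")
    config = config or FoldConfig()
    if structure is None:
        structure = fold_mfe(seq, config)
    stats = analyze_structure(structure)
    ens = ensemble_stats(seq, config)

    flags: dict = {}
    values: dict[str, float] = {}
    for name, v in zip(TRIPLET_NAMES, triplet_features(seq, structure)):
        values[name] = float(v)
    values.update(sequential_features(seq, stats))
    values.update(
        thermodynamic_features(
            seq, structure, stats, shuffles=shuffles, seed=seed, config=config, flags=flags
        )
    )
    values.update(basepair_features(seq, structure, stats, flags=flags))
    values["Frequency"] = ens.freq
    values["Diversity"] = ens.diversity
    return FeatureVector(
        values=np.array([values[name] for name in FEATURE_NAMES]), flags=flags
    )


def _record_seed(base_seed: int, record_id: str) -> int:
    """Stable per-record shuffle seed, independent of batch composition."""
    digest = hashlib.sha256(f"{base_seed}:{record_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def extract_features(
    sequences: list[RnaSequence],
    config: FoldConfig | None = None,
    shuffles: int = 1000,
    seed: int = 0,
    include_flags: bool = False,
) -> pd.DataFrame:
    """Feature table for a batch of sequences (rows indexed by record id).

    Per-record randomness is keyed to the record id and ``seed``, so batch
    extraction equals record-by-record extraction regardless of order.
    With ``include_flags``, boolean ``*_degenerate`` columns mark
    zero-denominator features.
    """
    rows = []
    flag_rows = []
    for seq in sequences:
        fv = extract_all(
            seq, config=config, shuffles=shuffles, seed=_record_seed(seed, seq.id)
        )
        rows.append(fv.as_series(name=seq.id))
        flag_rows.append(fv.flags)
    table = pd.DataFrame(rows)
    table.index.name = "id"
    if include_flags:
        flagged = sorted({name for f in flag_rows for name in f})
        for name in flagged:
            table[f"{name}_degenerate"] = [name in f for f in flag_rows]
    return table


class HairpinFeaturizer(TransformerMixin, BaseEstimator):
    """Transform RNA sequences into the 54-feature matrix.

    scikit-learn transformer over lists of :class:`RnaSequence` (or raw
    strings, which get positional ids).  Stateless apart from parameters:
    ``fit`` only validates and records the output schema.

    Parameters
    ----------
    backend : str
        Folding backend ("builtin" or a registered external backend).
    min_loop : int
        Minimum hairpin loop size in nt.
    kT : float
        Boltzmann temperature of the built-in ensemble model.
    temperature : float
        Celsius temperature for external backends.
    shuffles : int
        Dinucleotide shuffles per record for zP/zG.
    random_state : int
        Base seed for the shuffle null.
    """

    def __init__(
        self,
        backend: str = "builtin",
        min_loop: int = 3,
        kT: float = 1.0,
        temperature: float = 37.0,
        shuffles: int = 1000,
        random_state: int = 0,
    ):
        self.backend = backend
        self.min_loop = min_loop
        self.kT = kT
        self.temperature = temperature
        self.shuffles = shuffles
        self.random_state = random_state

    def _fold_config(self) -> FoldConfig:
        return FoldConfig(
            backend=self.backend,
            min_loop=self.min_loop,
            kT=self.kT,
            temperature=self.temperature,
        )

    def _coerce(self, X) -> list[RnaSequence]:
        out = []
        for k, item in enumerate(X):
            if isinstance(item, RnaSequence):
                out.append(item)
            else:
                out.append(RnaSequence.from_raw(f"seq_{k}", str(item)))
        return out

    def fit(self, X, y=None):
        self._fold_config()  # validates parameters
        self.n_features_in_ = 0  # sequences, not a feature matrix
        self.feature_names_out_ = np.array(FEATURE_NAMES, dtype=object)
        return self

    def transform(self, X) -> np.ndarray:
        sequences = self._coerce(X)
        table = extract_features(
            sequences,
            config=self._fold_config(),
            shuffles=self.shuffles,
            seed=self.random_state,
        )
        return table.to_numpy()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(FEATURE_NAMES, dtype=object)
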