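"""Secondary-structure prediction: built-in folder and external backends.

The built-in folder is a maximum-pair-score dynamic program (Nussinov-style)
over Watson-Crick plus G-U wobble pairs, with a minimum hairpin-loop size and
graded pair scores (default G-C=3, A-U=2, G-U=1 reflecting thermodynamic
stacking order).  The reported ``mfe`` is the *negated* optimal score so that
lower means more stable, matching the sign convention of thermodynamic
folders.

Ensemble statistics use the same decomposition as a partition function: the
recursion

    Z(i, j) = Z(i+1, j) + sum_k  w(i, k) * Z(i+1, k-1) * Z(k+1, j)

(first residue unpaired, or paired with some k) generates every nested
structure exactly once, so Boltzmann-weighting each pair with
``w = exp(score/kT)`` yields exact ensemble frequencies and, via the matching
outside recursion, exact base-pair probabilities (McCaskill's scheme on the
simplified energy model).

An external thermodynamic backend can be registered by name; the adapter for
the Vienna RNA package's Python bindings is registered automatically when the
``RNA`` module is importable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from .exceptions import BackendUnavailableError, StructureParseError
from .io import RnaSequence
from .structure import pair_table_from_dotbracket

__all__ = [
    "FoldConfig",
    "SecondaryStructure",
    "EnsembleStats",
    "fold_mfe",
    "ensemble_stats",
    "register_backend",
]

DEFAULT_PAIR_SCORES = {"GC": 3.0, "AU": 2.0, "GU": 1.0}


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket string, 1-based pair table, and free energy / score."""

    dotbracket: str
    pairs: tuple[int, ...]  # pairs[0] unused; pairs[i] = j or 0
    mfe: float

    @classmethod
    def from_dotbracket(cls, dotbracket: str, mfe: float) -> "SecondaryStructure":
        return cls(
            dotbracket=dotbracket,
            pairs=tuple(pair_table_from_dotbracket(dotbracket)),
            mfe=mfe,
        )

    @property
    def n_bp(self) -> int:
        return sum(1 for i in range(1, len(self.pairs)) if self.pairs[i] > i)


@dataclass(frozen=True)
class EnsembleStats:
    """Boltzmann-ensemble summary.

    ``freq``: probability of the MFE structure in the ensemble, in (0, 1].
    ``diversity``: sum over i<j of P(i,j)*(1 - P(i,j)), the variance-form
    base-pair diversity; 0 iff the ensemble holds a single structure.
    """

    freq: float
    diversity: float


@dataclass(frozen=True)
class FoldConfig:
    """Folding configuration.

    ``backend``: "builtin" (default) or a registered external backend name
    ("viennarna"/"external").  ``min_loop`` is the minimum hairpin-loop size in
    nt (steric minimum 3).  ``pair_scores`` and ``kT`` drive the built-in
    folder; ``temperature`` (Celsius) is passed to external backends.
    """

    backend: str = "builtin"
    min_loop: int = 3
    pair_scores: dict = field(default_factory=lambda: dict(DEFAULT_PAIR_SCORES))
    kT: float = 1.0
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")
        if any(v <= 0 for v in self.pair_scores.values()):
            raise ValueError("pair scores must be > 0")

    def score_of(self, a: str, b: str) -> float | None:
        """Pair score for residues ``a``-``b``; None if not pairable."""
        key = a + b if a < b else b + a
        # keys normalised: AU, CG -> GC, GU
        if key == "AU":
            return self.pair_scores["AU"]
        if key == "CG":
            return self.pair_scores["GC"]
        if key == "GU":
            return self.pair_scores["GU"]
        return None


# ---------------------------------------------------------------------------
# Built-in folder
# ---------------------------------------------------------------------------


def _pair_partners(s: str, config: FoldConfig) -> list[list[tuple[int, float]]]:
    """For each 0-based i, the list of (k, score) with k > i + min_loop."""
    L = len(s)
    out: list[list[tuple[int, float]]] = [[] for _ in range(L)]
    for i in range(L):
        for k in range(i + config.min_loop + 1, L):
            sc = config.score_of(s[i], s[k])
            if sc is not None:
                out[i].append((k, sc))
    return out


def _fill_dp(s: str, config: FoldConfig) -> tuple[list[list[float]], list]:
    L = len(s)
    partners = _pair_partners(s, config)
    M = [[0.0] * L for _ in range(L)]
    for span in range(config.min_loop + 1, L):
        for i in range(L - span):
            j = i + span
            Mi1 = M[i + 1]
            best = Mi1[j]
            for k, sc in partners[i]:
                if k > j:
                    break
                cand = sc + (Mi1[k - 1] if k > i + 1 else 0.0) + (
                    M[k + 1][j] if k < j else 0.0
                )
                if cand > best:
                    best = cand
            M[i][j] = best
    return M, partners


def _fold_builtin(seq: RnaSequence, config: FoldConfig) -> SecondaryStructure:
    s = seq.residues
    L = len(s)
    if L < 2:
        return SecondaryStructure.from_dotbracket("." * L, mfe=0.0)
    M, partners = _fill_dp(s, config)

    # Traceback: prefer pairing i (largest co-optimal partner k) over leaving
    # i unpaired.  Determinism among co-optimal structures; the outermost
    # partner keeps a designed stem-loop in one piece instead of splitting it
    # into co-optimal branched alternatives.
    pairs = [0] * (L + 1)
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = M[i][j]
        if target == 0.0:
            continue
        chosen = None
        for k, sc in reversed(partners[i]):
            if k > j:
                continue
            cand = sc + (M[i + 1][k - 1] if k > i + 1 else 0.0) + (
                M[k + 1][j] if k < j else 0.0
            )
            if cand == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs[i + 1] = chosen + 1
            pairs[chosen + 1] = i + 1
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))

    db = "".join(
        "(" if pairs[p] > p else (")" if pairs[p] else ".")
        for p in range(1, L + 1)
    )
    return SecondaryStructure(dotbracket=db, pairs=tuple(pairs), mfe=-M[0][L - 1])


def _inside_outside(seq: RnaSequence, config: FoldConfig) -> tuple[float, dict]:
    """Partition function and exact pair probabilities, 0-based keys."""
    s = seq.residues
    L = len(s)
    kT = config.kT
    partners = _pair_partners(s, config)
    weights = [[(k, math.exp(sc / kT)) for k, sc in row] for row in partners]

    # Inside: Z[i][j] over interval [i, j]; empty interval = 1.
    Z = [[1.0] * L for _ in range(L)]

    def z(a: int, b: int) -> float:
        return Z[a][b] if a <= b else 1.0

    for span in range(1, L):
        for i in range(L - span):
            j = i + span
            total = Z[i + 1][j] if i + 1 <= j else 1.0
            for k, w in weights[i]:
                if k > j:
                    break
                total += w * z(i + 1, k - 1) * z(k + 1, j)
            Z[i][j] = total
    Z_total = Z[0][L - 1]

    # Outside sweep over intervals in decreasing span; accumulate P(i, k).
    E = [[0.0] * L for _ in range(L)]
    E[0][L - 1] = 1.0
    P: dict[tuple[int, int], float] = {}
    for span in range(L - 1, 0, -1):
        for i in range(L - span):
            j = i + span
            e = E[i][j]
            if e == 0.0:
                continue
            E[i + 1][j] += e
            for k, w in weights[i]:
                if k > j:
                    break
                inner = z(i + 1, k - 1)
                right = z(k + 1, j)
                P[(i, k)] = P.get((i, k), 0.0) + e * w * inner * right / Z_total
                if i + 1 <= k - 1:
                    E[i + 1][k - 1] += e * w * right
                if k + 1 <= j:
                    E[k + 1][j] += e * w * inner
    return Z_total, P


def _ensemble_builtin(seq: RnaSequence, config: FoldConfig) -> EnsembleStats:
    if len(seq) < 2:
        return EnsembleStats(freq=1.0, diversity=0.0)
    Z_total, P = _inside_outside(seq, config)
    mfe_structure = _fold_builtin(seq, config)
    freq = math.exp(-mfe_structure.mfe / config.kT) / Z_total
    diversity = sum(p * (1.0 - p) for p in P.values())
    return EnsembleStats(freq=min(freq, 1.0), diversity=max(diversity, 0.0))


def pair_probabilities(seq: RnaSequence, config: FoldConfig | None = None) -> dict:
    """Exact base-pair probabilities {(i, j) 1-based: P} under the built-in model."""
    config = config or FoldConfig()
    if config.backend != "builtin":
        raise ValueError("pair_probabilities is only defined for the builtin backend")
    if len(seq) < 2:
        return {}
    _, P = _inside_outside(seq, config)
    return {(i + 1, k + 1): p for (i, k), p in P.items()}


# ---------------------------------------------------------------------------
# External backends
# ---------------------------------------------------------------------------

#: name -> callable(sequence, temperature) -> (dotbracket, mfe, freq, diversity)
_BACKENDS: dict[str, Callable] = {}


def register_backend(name: str, adapter: Callable) -> None:
    """Register an external folding adapter under ``name``.

    The adapter contract: ``adapter(sequence: str, temperature: float)`` must
    return ``(dotbracket, mfe_kcal_mol, freq, diversity)``.
    """
    _BACKENDS[name] = adapter


def _viennarna_adapter(sequence: str, temperature: float):
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - RNA present in CI image
        raise BackendUnavailableError(
            "the 'viennarna' backend requires the RNA python module; install "
            "the Vienna RNA package or use backend='builtin'"
        ) from exc
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(sequence, md)
    db, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    _, ensemble_energy = fc.pf()
    kT = 0.0019872041 * (273.15 + temperature)  # kcal/mol
    freq = math.exp((ensemble_energy - mfe) / kT)
    diversity = fc.mean_bp_distance()
    return db, float(mfe), float(freq), float(diversity)


register_backend("viennarna", _viennarna_adapter)
register_backend("external", _viennarna_adapter)


def _external(seq: RnaSequence, config: FoldConfig):
    if config.backend not in _BACKENDS:
        raise BackendUnavailableError(
            f"unknown folding backend {config.backend!r}; registered: "
            f"{sorted(_BACKENDS)} (or use 'builtin')"
        )
    return _BACKENDS[config.backend](seq.residues, config.temperature)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def fold_mfe(seq: RnaSequence, config: FoldConfig | None = None) -> SecondaryStructure:
    """Predict the MFE (maximum-score) structure of ``seq``."""
    config = config or FoldConfig()
    if config.backend == "builtin":
        return _fold_builtin(seq, config)
    db, mfe, _, _ = _external(seq, config)
    try:
        return SecondaryStructure.from_dotbracket(db, mfe=mfe)
    except StructureParseError as exc:
        raise StructureParseError(
            f"backend {config.backend!r} returned an invalid structure: {exc}"
        ) from exc


def ensemble_stats(seq: RnaSequence, config: FoldConfig | None = None) -> EnsembleStats:
    """Boltzmann-ensemble frequency of the MFE structure and pair diversity."""
    config = config or FoldConfig()
    if config.backend == "builtin":
        return _ensemble_builtin(seq, config)
    _, _, freq, diversity = _external(seq, config)
    return EnsembleStats(freq=freq, diversity=diversity)
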