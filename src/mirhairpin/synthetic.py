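"""Synthetic data generation.

Two kinds of records are generated, mirroring the benchmark construction used
for viral pre-miRNA classifiers:

* *positive-like* single-hairpin sequences: a random 5' arm, a short terminal
  loop, and the reverse complement of the arm, with optional point mutations
  that introduce the bulges and wobbles real precursors carry.  Defaults
  (stem 12 bp, loop 6 nt, 5% mutation rate) give ~30-nt stem-loops with the
  long-stem character of miRNA precursors at small, testable size.
* *negative-like* fragments: either dinucleotide-preserving shuffles of given
  sequences (composition-matched, structure-free) or 120-nt fragments sampled
  uniformly from a (synthetic or real) genome, matching how genomic negative
  sets are drawn.
"""

from __future__ import annotations

import numpy as np

from .io import RnaSequence, sample_negative_fragments
from .shuffle import dinucleotide_shuffle

__all__ = [
    "reverse_complement",
    "generate_synthetic_hairpins",
    "generate_shuffled_negatives",
    "generate_random_genome",
]

_RC = str.maketrans("ACGU", "UGCA")
_BASES = "ACGU"


def reverse_complement(s: str) -> str:
    """Reverse complement in RNA space (A<->U, G<->C)."""
    return s.translate(_RC)[::-1]


def generate_synthetic_hairpins(
    n: int,
    stem_length: int = 12,
    loop_length: int = 6,
    mutation_rate: float = 0.05,
    seed: int = 0,
    arm: str | None = None,
    id_prefix: str = "hp",
) -> list[RnaSequence]:
    """Generate single-hairpin sequences: arm + loop + revcomp(arm).

    ``arm`` pins the 5' arm to a fixed sequence (mainly for tests); otherwise
    arms are drawn uniformly over A/C/G/U.  Each unmutated molecule is
    verified to fold (built-in folder, defaults) into exactly the designed
    stem-loop — occasional random draws whose loop residues recruit extra
    pairs into a branched optimum are redrawn, so the generator's contract
    (the sequence *is* a single hairpin) holds for every record.  Mutations
    are then i.i.d. per-base substitutions (to one of the three other bases)
    applied to the assembled molecule, so at ``mutation_rate=0`` the two arms
    are exactly reverse complementary.  Total length is
    ``2*stem_length + loop_length``.
    """
    from .folding import fold_mfe  # deferred: keeps module import cheap

    if stem_length < 4:
        raise ValueError("stem_length must be >= 4")
    if loop_length < 3:
        raise ValueError("loop_length must be >= 3 (steric minimum for a hairpin loop)")
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    if arm is not None and len(arm) != stem_length:
        raise ValueError("fixed arm length must equal stem_length")

    designed = "(" * stem_length + "." * loop_length + ")" * stem_length
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n):
        for _ in range(1000):
            arm5 = arm if arm is not None else "".join(
                _BASES[i] for i in rng.integers(0, 4, size=stem_length)
            )
            loop = "".join(_BASES[i] for i in rng.integers(0, 4, size=loop_length))
            clean = RnaSequence(id=f"{id_prefix}_{k:04d}", residues=arm5 + loop + reverse_complement(arm5))
            if fold_mfe(clean).dotbracket == designed:
                break
        else:
            raise RuntimeError(
                "could not draw a sequence folding into the designed stem-loop; "
                "check stem_length/loop_length (or the pinned arm)"
            )
        seq = list(clean.residues)
        if mutation_rate > 0:
            hits = np.flatnonzero(rng.random(len(seq)) < mutation_rate)
            for pos in hits:
                alternatives = _BASES.replace(seq[pos], "")
                seq[pos] = alternatives[rng.integers(3)]
        records.append(RnaSequence(id=clean.id, residues="".join(seq)))
    return records


def generate_shuffled_negatives(
    sequences: list[RnaSequence], seed: int = 0, id_prefix: str = "shuf"
) -> list[RnaSequence]:
    """Dinucleotide-preserving shuffles of the given sequences.

    Each output record is composition-matched to its source but carries no
    designed base-pairing, the standard structure-free null.
    """
    rng = np.random.default_rng(seed)
    return [
        RnaSequence(
            id=f"{id_prefix}_{k:04d}", residues=dinucleotide_shuffle(s.residues, rng)
        )
        for k, s in enumerate(sequences)
    ]


def generate_random_genome(
    length: int, gc: float = 0.5, seed: int = 0, id: str = "synthetic_genome"
) -> RnaSequence:
    """An i.i.d. random genome with the given GC fraction (for fragment sampling)."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    residues = "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))
    return RnaSequence(id=id, residues=residues)


def generate_genome_fragment_negatives(
    n: int,
    genome_length: int = 20000,
    fragment_length: int = 120,
    gc: float = 0.5,
    seed: int = 0,
) -> list[RnaSequence]:
    """120-nt fragments sampled uniformly from a synthetic genome."""
    genome = generate_random_genome(genome_length, gc=gc, seed=seed)
    return sample_negative_fragments(
        genome, n=n, fragment_length=fragment_length, seed=seed + 1
    )
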