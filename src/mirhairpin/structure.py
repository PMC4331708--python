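"""Secondary-structure topology: pair tables and stem/loop statistics.

All statistics here depend only on the pairing topology (the dot-bracket
string), not on sequence content; pair-type tallies live in
:mod:`mirhairpin.features`.

Definitions (conventions documented in docs/methods.md):

* a *stem run* is a maximal set of stacked pairs (i,j), (i+1,j-1), ...; any
  bulge or interior loop breaks the run;
* ``n_stems`` counts runs of more than three pairs (i.e. length >= 4),
  the miPred-style stem definition;
* a *hairpin (terminal) loop* is the unpaired interval enclosed by a pair
  with no pairs inside it; ``n_loops`` counts these by default;
* ``hairpin_span`` is the length in nt from the outermost pair enclosing the
  largest terminal loop to its partner; ``terminal_loop_len`` is the size of
  that largest terminal loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .exceptions import StructureParseError

if TYPE_CHECKING:  # pragma: no cover
    from .folding import SecondaryStructure

__all__ = [
    "pair_table_from_dotbracket",
    "StructureStats",
    "analyze_structure",
    "classify_hairpin_like",
]


def pair_table_from_dotbracket(dotbracket: str) -> list[int]:
    """1-based pair table: ``p[i] = j`` if (i, j) paired, else 0; ``p[0] = 0``.

    Raises :class:`StructureParseError` at the first offending position for
    unbalanced strings or foreign characters.
    """
    p = [0] * (len(dotbracket) + 1)
    stack: list[int] = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureParseError(
                    f"unbalanced ')' at position {pos} in {dotbracket!r}"
                )
            opener = stack.pop()
            p[opener] = pos
            p[pos] = opener
        elif ch != ".":
            raise StructureParseError(
                f"invalid character {ch!r} at position {pos} in {dotbracket!r}"
            )
    if stack:
        raise StructureParseError(
            f"unbalanced '(' at position {stack[0]} in {dotbracket!r}"
        )
    return p


@dataclass(frozen=True)
class StructureStats:
    """Topological summary of one secondary structure."""

    n_bp: int
    stem_runs: tuple[int, ...]
    n_stems: int
    n_loops: int
    consec_bp: int
    hairpin_span: int
    terminal_loop_len: int
    is_hairpin_like: bool


def _stem_runs(pairs: list[tuple[int, int]]) -> list[int]:
    runs: list[int] = []
    current = 0
    prev: tuple[int, int] | None = None
    for i, j in pairs:
        if prev is not None and i == prev[0] + 1 and j == prev[1] - 1:
            current += 1
        else:
            if current:
                runs.append(current)
            current = 1
        prev = (i, j)
    if current:
        runs.append(current)
    return runs


def analyze_structure(
    structure: "SecondaryStructure",
    min_stem_pairs: int = 4,
    count_all_loops: bool = False,
) -> StructureStats:
    """Compute :class:`StructureStats` from a structure's pair table.

    ``min_stem_pairs`` is the minimum run length counted as a stem (default 4,
    i.e. more than three contiguous pairs).  With ``count_all_loops`` the loop
    count includes bulge/interior/multibranch loops in addition to terminal
    loops (the default counts terminal loops only).
    """
    p = structure.pairs
    L = len(structure.dotbracket)
    pairs = [(i, p[i]) for i in range(1, L + 1) if p[i] > i]

    runs = _stem_runs(pairs)
    n_bp = len(pairs)
    consec_bp = max(runs, default=0)
    n_stems = sum(1 for r in runs if r >= min_stem_pairs)

    # Terminal (hairpin) loops: closing pair with no pairs strictly inside.
    terminal: list[tuple[int, int]] = []
    for i, j in pairs:
        if all(p[k] == 0 for k in range(i + 1, j)):
            terminal.append((i, j))
    n_terminal = len(terminal)

    hairpin_span = 0
    terminal_loop_len = 0
    if terminal:
        i0, j0 = max(terminal, key=lambda ij: (ij[1] - ij[0], -ij[0]))
        terminal_loop_len = j0 - i0 - 1
        # Walk outward to the outermost pair enclosing this loop.
        a, b = i0, j0
        for i, j in reversed(pairs):
            if i < a and j > b:
                a, b = i, j
        hairpin_span = b - a + 1

    n_loops = n_terminal
    if count_all_loops:
        terminal_set = set(terminal)
        extra = 0
        for i, j in pairs:
            if (i, j) in terminal_set:
                continue
            # Children: pairs directly enclosed, not nested in a deeper pair.
            k = i + 1
            children = 0
            unpaired = 0
            while k < j:
                if p[k] > k:
                    children += 1
                    k = p[k] + 1
                else:
                    unpaired += p[k] == 0
                    k += 1
            if children >= 2 or (children == 1 and unpaired > 0):
                extra += 1  # multibranch or interior/bulge loop
        n_loops = n_terminal + extra

    return StructureStats(
        n_bp=n_bp,
        stem_runs=tuple(runs),
        n_stems=n_stems,
        n_loops=n_loops,
        consec_bp=consec_bp,
        hairpin_span=hairpin_span,
        terminal_loop_len=terminal_loop_len,
        is_hairpin_like=(n_bp >= 1 and n_terminal == 1),
    )


def classify_hairpin_like(stats: StructureStats) -> bool:
    """True iff the structure is a single stem-loop.

    A structure is hairpin-like when it pairs at all and contains exactly one
    terminal loop (which rules out multibranch topologies, since every branch
    terminates in its own hairpin loop).
    """
    return stats.is_hairpin_like
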