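"""Compact letter display (CLD) by the insert-and-absorb algorithm.

Given all pairwise p-values among a set of levels (here, wintering
groups) and a significance level alpha, a CLD assigns each level a set of
letters such that two levels share at least one letter if and only if
they are *not* significantly different at alpha.  The insert step splits
every letter column containing a significant pair; the absorb step
deletes columns that became subsets of others, keeping the letter count
minimal.

``alpha_sweep`` repeats the grouping over a grid of alpha levels and
reports, per pair, the bracketing grid interval across which the pair's
separation flips — the natural way to report a non-significant contrast
as a p-value range when the display itself only answers at fixed alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from string import ascii_lowercase

__all__ = ["LetterGrouping", "compact_letter_display", "alpha_sweep_grouping"]


@dataclass
class LetterGrouping:
    """Letters per level at one significance level."""

    alpha: float
    letters: dict[str, str]

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _check_matrix(levels: list[str], p_values: dict) -> dict[frozenset, float]:
    pmat = {}
    for a, b in combinations(levels, 2):
        key = frozenset((a, b))
        if (a, b) in p_values:
            p = p_values[(a, b)]
        elif (b, a) in p_values:
            p = p_values[(b, a)]
        elif key in p_values:
            p = p_values[key]
        else:
            raise ValueError(f"pairwise p-value missing for ({a}, {b})")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} for ({a}, {b}) outside [0, 1]")
        pmat[key] = float(p)
    return pmat


def compact_letter_display(
    levels: list[str], p_values: dict, alpha: float = 0.05
) -> LetterGrouping:
    """Insert-and-absorb letter assignment.

    ``p_values`` maps level pairs (tuples in either order, or frozensets)
    to p-values; the matrix must be complete.  Levels share a letter iff
    their pairwise p-value is >= alpha.
    """
    levels = list(levels)
    pmat = _check_matrix(levels, p_values)
    columns: list[set[str]] = [set(levels)]
    # deterministic insert order: by level order, then partner order
    for a, b in combinations(levels, 2):
        if pmat[frozenset((a, b))] >= alpha:
            continue
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another
        columns = [
            c for i, c in enumerate(new_cols)
            if c and not any(c < d or (c == d and i > j)
                             for j, d in enumerate(new_cols) if i != j)
        ]
    # letter order follows the earliest level each column contains
    columns.sort(key=lambda c: min(levels.index(x) for x in c))
    letters = {lv: "" for lv in levels}
    for letter, col in zip(ascii_lowercase, columns):
        for lv in levels:
            if lv in col:
                letters[lv] += letter
    return LetterGrouping(alpha=alpha, letters=letters)


@dataclass
class PairBracket:
    """Grid interval bracketing the alpha at which a pair's separation flips.

    ``low`` is the largest grid alpha at which the pair is still grouped
    together (None if separated over the whole grid) and ``high`` the
    smallest at which it separates (None if never separated on the grid).
    Read "low < p < high" for an interior flip.
    """

    pair: tuple[str, str]
    p_value: float
    low: float | None
    high: float | None


def alpha_sweep_grouping(
    levels: list[str], p_values: dict, alpha_grid: list[float]
) -> tuple[list[LetterGrouping], list[PairBracket]]:
    """Letter groupings along an increasing alpha grid, plus flip brackets.

    A pair is separated at alpha iff p < alpha, so separation is monotone
    along the grid; the bracket for a pair is the adjacent grid interval
    containing its p-value.
    """
    grid = list(alpha_grid)
    if any(not 0 < a < 1 for a in grid) or any(
        b <= a for a, b in zip(grid, grid[1:])
    ):
        raise ValueError("alpha_grid must be strictly increasing within (0, 1)")
    groupings = [compact_letter_display(levels, p_values, alpha=a) for a in grid]
    pmat = _check_matrix(list(levels), p_values)
    brackets = []
    for a, b in combinations(list(levels), 2):
        p = pmat[frozenset((a, b))]
        below = [g for g in grid if g <= p]   # grouped together at these alphas
        above = [g for g in grid if g > p]    # separated at these alphas
        brackets.append(
            PairBracket(
                pair=(a, b),
                p_value=p,
                low=max(below) if below else None,
                high=min(above) if above else None,
            )
        )
    return groupings, brackets
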