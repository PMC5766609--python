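"""Analysis of selected clones: mutation calling against the parent
hormone backbone, sub-library assignment, positivity thresholds and
per-round enrichment summaries.

Peptide positions are 1-based on the parent (glucagon numbering H1..T29);
N-terminal extension residues are labeled -2, -1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .design import DopedDesign

__all__ = [
    "GLUCAGON",
    "MutationCall",
    "WindowLayout",
    "DEFAULT_LAYOUT",
    "default_sublibrary_designs",
    "call_mutations",
    "apply_mutations",
    "format_calls",
    "assign_sublibrary",
    "positivity_call",
    "hit_summary",
    "enrichment_table",
]

#: wild-type human glucagon, 1-letter codes, positions 1..29
GLUCAGON = "HSQGTFTSDYSKYLDSRRAQDFVQWLMNT"


@dataclass(frozen=True)
class MutationCall:
    """A single substitution (or extension residue) relative to the parent.

    ``wt`` is None for extension calls (there is no parent residue at
    negative positions).
    """

    position: int
    wt: str | None
    observed: str

    def __post_init__(self):
        if self.position == 0:
            raise ValueError("position labels are 1-based (or negative)")
        if self.position < 0:
            if self.wt is not None:
                raise ValueError("extension calls carry wt=None")
        elif self.wt == self.observed:
            raise ValueError("substitution call with wt == observed")

    def __str__(self) -> str:
        if self.position < 0:
            return f"{self.observed}({self.position})"
        return f"{self.wt}{self.position}{self.observed}"


class AlignmentError(ValueError):
    pass


def call_mutations(peptide: str, parent: str = GLUCAGON,
                   max_extension: int = 2) -> list[MutationCall]:
    """Call substitutions of ``peptide`` relative to ``parent``.

    Equal lengths are compared position-wise.  A peptide longer by
    ``e <= max_extension`` residues is read as an N-terminal extension:
    its first ``e`` residues become extension calls at labels -e..-1 and
    the remainder is compared position-wise.  Calls are returned sorted
    by position.
    """
    L, Lp = len(parent), len(peptide)
    if Lp < L or Lp > L + max_extension:
        raise AlignmentError(
            f"peptide length {Lp} incompatible with parent length {L} "
            f"(+<= {max_extension} extension)")
    e = Lp - L
    calls = [MutationCall(position=i - e, wt=None, observed=peptide[i])
             for i in range(e)]
    for i in range(L):
        if peptide[e + i] != parent[i]:
            calls.append(MutationCall(position=i + 1, wt=parent[i],
                                      observed=peptide[e + i]))
    return sorted(calls, key=lambda c: c.position)


def apply_mutations(parent: str, calls: Sequence[MutationCall]) -> str:
    """Inverse of :func:`call_mutations`: rebuild the peptide."""
    seen: dict[int, MutationCall] = {}
    for c in calls:
        if c.position in seen:
            raise ValueError(f"conflicting calls at position {c.position}")
        seen[c.position] = c
    ext = sorted((p for p in seen if p < 0))
    if ext and ext != list(range(ext[0], 0)):
        raise ValueError("extension calls must be contiguous up to -1")
    residues = list(parent)
    for c in seen.values():
        if c.position > 0:
            if c.position > len(parent):
                raise ValueError(f"position {c.position} beyond parent")
            if parent[c.position - 1] != c.wt:
                raise ValueError(
                    f"call {c} disagrees with parent residue "
                    f"{parent[c.position - 1]}{c.position}")
            residues[c.position - 1] = c.observed
    prefix = "".join(seen[p].observed for p in ext)
    return prefix + "".join(residues)


def format_calls(calls: Sequence[MutationCall]) -> str:
    return ", ".join(str(c) for c in calls)


@dataclass(frozen=True)
class WindowLayout:
    """Named sub-libraries, each an ordered set of randomized positions."""

    windows: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self):
        object.__setattr__(self, "windows", tuple(
            (name, tuple(pos)) for name, pos in self.windows))
        for name, pos in self.windows:
            if len(set(pos)) != len(pos):
                raise ValueError(f"duplicate positions in window {name}")

    def names(self) -> list[str]:
        return [name for name, _ in self.windows]

    def positions(self, name: str) -> tuple[int, ...]:
        for n, pos in self.windows:
            if n == name:
                return pos
        raise KeyError(name)


def _window(lo: int, hi: int, shared=(27, 28)) -> tuple[int, ...]:
    pos = list(range(lo, hi + 1))
    pos += [p for p in shared if p not in pos]
    return tuple(pos)


#: Four 7-residue windows augmented with the shared C-terminal positions
#: {27, 28}, plus the N-terminal extension sub-library.  The fourth window
#: already contains 27 and 28, so it has 7 randomized positions after
#: deduplication; clones whose substitutions fit no window are flagged
#: inconsistent rather than rejected.
DEFAULT_LAYOUT = WindowLayout(windows=(
    ("sub1", _window(1, 7)),
    ("sub2", _window(8, 14)),
    ("sub3", _window(15, 21)),
    ("sub4", _window(22, 28)),
    ("ext", (-2, -1, 1, 2, 3, 4, 5, 27, 28)),
))


def default_sublibrary_designs(parent: str = GLUCAGON,
                               p_wt: float = 0.45,
                               n_alternatives: int = 18,
                               library_size: int = 60_000_000,
                               layout: WindowLayout = DEFAULT_LAYOUT,
                               ) -> list[DopedDesign]:
    """One :class:`DopedDesign` per sub-library of the layout."""
    return [DopedDesign(parent=parent, randomized_positions=pos, p_wt=p_wt,
                        n_alternatives=n_alternatives,
                        library_size=library_size, name=name)
            for name, pos in layout.windows]


def assign_sublibrary(calls: Sequence[MutationCall],
                      layout: WindowLayout = DEFAULT_LAYOUT) -> list[str]:
    """Sub-libraries whose position set contains every called position.

    Extension calls are only compatible with windows that include the
    negative labels.  An empty result means the clone is inconsistent
    with the declared layout.
    """
    needed = {c.position for c in calls}
    return [name for name, pos in layout.windows if needed <= set(pos)]


def positivity_call(signals: Mapping[str, float] | Sequence[float],
                    threshold: float) -> list[bool] | dict[str, bool]:
    """Positivity = signal strictly above an explicit threshold."""
    if isinstance(signals, Mapping):
        return {k: v > threshold for k, v in signals.items()}
    return [v > threshold for v in signals]


def hit_summary(calls_by_receptor: Mapping[str, Sequence[bool]]) -> dict:
    """Co-positive / single-positive / negative counts across receptors.

    ``calls_by_receptor`` maps receptor name -> per-clone positivity
    booleans (same clone order in each).  Fractions are exact; the
    ``formatted`` entries render "n/N (p%)" with the percentage to the
    nearest integer.
    """
    receptors = list(calls_by_receptor)
    lengths = {len(v) for v in calls_by_receptor.values()}
    if len(lengths) != 1:
        raise ValueError("receptor call vectors differ in length")
    n = lengths.pop()
    co = single = neg = 0
    for flags in zip(*calls_by_receptor.values()):
        k = sum(flags)
        if k == len(receptors):
            co += 1
        elif k > 0:
            single += 1
        else:
            neg += 1

    def fmt(c: int) -> str:
        pct = 0.0 if n == 0 else 100.0 * c / n
        return f"{c}/{n} ({pct:.0f}%)"

    return {
        "n": n,
        "receptors": receptors,
        "co_positive": co,
        "single_positive": single,
        "negative": neg,
        "co_positive_fraction": co / n if n else 0.0,
        "single_positive_fraction": single / n if n else 0.0,
        "negative_fraction": neg / n if n else 0.0,
        "formatted": {"co_positive": fmt(co), "single_positive": fmt(single),
                      "negative": fmt(neg)},
    }


def enrichment_table(pools: Sequence) -> "pandas.DataFrame":
    """Per-variant frequencies and round-over-round fold changes.

    ``pools`` are :class:`~dopedlib.simulate.PoolState` objects (or any
    object with a ``counts`` mapping key -> count), ordered by round.
    Fold change is freq_r / freq_{r-1}; a variant absent in the previous
    round is flagged ``new`` (fold change NaN).
    """
    import numpy as np
    import pandas as pd

    if len(pools) < 2:
        raise ValueError("need at least two pools")
    counts = [dict(p.counts if hasattr(p, "counts") else p) for p in pools]
    keys = sorted({k for c in counts for k in c}, key=str)
    freqs = []
    for c in counts:
        total = sum(c.values())
        freqs.append({k: c.get(k, 0) / total for k in keys})
    rows = []
    for k in keys:
        row: dict = {"variant": str(k)}
        for r, f in enumerate(freqs):
            row[f"freq_r{r}"] = f[k]
        for r in range(1, len(freqs)):
            prev, cur = freqs[r - 1][k], freqs[r][k]
            if prev == 0:
                row[f"fold_r{r}"] = np.nan
                row[f"flag_r{r}"] = "new" if cur > 0 else "absent"
            else:
                row[f"fold_r{r}"] = cur / prev
                row[f"flag_r{r}"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
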