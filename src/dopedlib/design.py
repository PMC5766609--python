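"""Closed-form statistics of a doped ("soft-randomized") peptide library.

A doped library randomizes ``m`` positions of a parent peptide; each
randomized position keeps the wild-type residue with probability ``p_wt``
and otherwise takes one of ``a`` alternative residues with equal weight.
The number of mutations per clone is therefore Binomial(m, 1 - p_wt),
which concentrates the physical library on few-mutation variants.

This module is the engine behind the library design table: per
mutation-class fraction, theoretical diversity, Poisson coverage of that
diversity at the physical library size, expected unique clones and average
duplication.  All counts are kept at full precision (exact integers for
diversity); rounding happens only at formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "DopedDesign",
    "MutationClassRow",
    "DesignTable",
    "mutation_class_fraction",
    "theoretical_diversity",
    "poisson_coverage",
    "exact_coverage",
    "expected_unique",
    "average_duplicates",
    "build_design_table",
    "pool_complexity",
]

#: 1-letter codes of the 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DopedDesign:
    """A doped-library design over a parent peptide.

    Parameters
    ----------
    parent
        Parent peptide, 1-letter codes, positions numbered 1..L.
    randomized_positions
        Ordered unique position labels. Labels 1..L address the parent;
        negative labels (-2, -1) address N-terminal extension slots and
        must be contiguous from -1 downward.
    p_wt
        Probability that a randomized position retains the wild-type
        residue (the doping level).
    n_alternatives
        Number of allowed non-wt residues per randomized position.
        Default 18 = 20 amino acids minus the wt residue minus Cys.
    library_size
        Physical clone count N of the library.
    """

    parent: str
    randomized_positions: tuple[int, ...]
    p_wt: float = 0.45
    n_alternatives: int = 18
    library_size: int = 60_000_000
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "randomized_positions",
                           tuple(self.randomized_positions))
        if any(aa not in AMINO_ACIDS for aa in self.parent):
            bad = set(self.parent) - set(AMINO_ACIDS)
            raise ValueError(f"parent contains non-standard residues: {bad}")
        pos = self.randomized_positions
        if len(set(pos)) != len(pos):
            raise ValueError("randomized_positions must be unique")
        L = len(self.parent)
        for p in pos:
            if p == 0 or p > L:
                raise ValueError(f"position label {p} outside 1..{L}")
        ext = sorted(p for p in pos if p < 0)
        if ext and ext != list(range(-len(ext), 0)):
            raise ValueError("extension slots must be contiguous from -1 down")
        if not 0.0 <= self.p_wt <= 1.0:
            raise ValueError("p_wt must lie in [0, 1]")
        if self.n_alternatives < 1:
            raise ValueError("n_alternatives must be >= 1")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")

    @property
    def m(self) -> int:
        """Number of randomized positions."""
        return len(self.randomized_positions)

    @property
    def extension_positions(self) -> tuple[int, ...]:
        return tuple(p for p in self.randomized_positions if p < 0)


@dataclass(frozen=True)
class MutationClassRow:
    """One mutation class (exactly ``k`` mutations from the parent)."""

    k: int
    fraction: float          # P(exactly k mutations)
    cumulative: float        # running sum over k' <= k
    physical_clones: float   # expected clones n_k = N * fraction (real-valued)
    diversity: int           # distinct sequences D_k (exact integer)
    coverage: float          # Poisson coverage of D_k by n_k
    unique_clones: float     # expected distinct variants U_k = D_k * coverage
    avg_duplicates: float    # n_k / U_k  (>= 1 whenever U_k > 0)


def _check_k(design: DopedDesign, k: int) -> None:
    if not 0 <= k <= design.m:
        raise ValueError(f"k={k} outside 0..{design.m}")


def mutation_class_fraction(design: DopedDesign, k: int) -> float:
    """Probability that a clone carries exactly ``k`` mutations.

    Binomial: C(m, k) * (1 - p_wt)^k * p_wt^(m - k).
    """
    _check_k(design, k)
    m, p = design.m, design.p_wt
    return math.comb(m, k) * (1.0 - p) ** k * p ** (m - k)


def theoretical_diversity(design: DopedDesign, k: int) -> int:
    """Distinct sequences with exactly ``k`` mutations: C(m, k) * a^k."""
    _check_k(design, k)
    return math.comb(design.m, k) * design.n_alternatives ** k


def poisson_coverage(n: float, D: float) -> float:
    """Poisson estimate of fractional completeness: 1 - exp(-n / D).

    The fraction of a diversity ``D`` expected to be observed at least
    once among ``n`` uniform random draws, under the Poisson occupancy
    approximation.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if D < 1:
        raise ValueError("D must be >= 1")
    return -math.expm1(-n / D)


def exact_coverage(n: float, D: float) -> float:
    """Exact occupancy expectation 1 - (1 - 1/D)^n.

    Alternative estimator to :func:`poisson_coverage`; used as an oracle
    in tests.  ``n`` may be real-valued (the expression extends smoothly).
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if D < 1:
        raise ValueError("D must be >= 1")
    if D == 1:
        return 0.0 if n == 0 else 1.0
    return -math.expm1(n * math.log1p(-1.0 / D))


def expected_unique(n: float, D: float,
                    coverage: str = "poisson") -> float:
    """Expected number of distinct variants among ``n`` draws from ``D``."""
    cov = poisson_coverage(n, D) if coverage == "poisson" else exact_coverage(n, D)
    return D * cov


def average_duplicates(n: float, unique: float) -> float:
    """Average copies per distinct variant, n / U."""
    if n < 0 or unique < 0:
        raise ValueError("inputs must be nonnegative")
    if unique == 0:
        raise ZeroDivisionError("average duplicates undefined for unique == 0")
    return n / unique


@dataclass
class DesignTable:
    """Mutation-class table for a doped design, plus totals."""

    design: DopedDesign
    rows: list[MutationClassRow]

    @property
    def total_fraction(self) -> float:
        return sum(r.fraction for r in self.rows)

    @property
    def total_physical_clones(self) -> float:
        return sum(r.physical_clones for r in self.rows)

    @property
    def total_unique_clones(self) -> float:
        return sum(r.unique_clones for r in self.rows)

    @property
    def total_diversity(self) -> int:
        return sum(r.diversity for r in self.rows)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame([vars(r) for r in self.rows])
        return df

    # -- display ---------------------------------------------------------
    # Percentages to 2 decimals, large counts to 3 significant figures in
    # scientific notation; coverage prints 100.00% once 1 - c < 5e-5, and
    # duplicates print "<<1" once coverage < 1% (duplication negligible).

    def format_rows(self) -> list[dict[str, str]]:
        out = []
        for r in self.rows:
            out.append({
                "k": "0 (wt)" if r.k == 0 else str(r.k),
                "fraction": _pct(r.fraction),
                "cumulative": _pct(min(r.cumulative, 1.0)),
                "physical_clones": _sci(r.physical_clones),
                "diversity": _sci(r.diversity),
                "coverage": _pct(r.coverage),
                "unique_clones": _sci(r.unique_clones),
                "avg_duplicates": ("<<1" if r.coverage < 0.01
                                   else f"{r.avg_duplicates:.2f}"),
            })
        # totals in the displayed table sum the *rounded* row values, so
        # the printed rows and the printed total stay arithmetically
        # consistent; the engine's totals keep full precision
        out.append({
            "k": "Sum:",
            "fraction": "100%",
            "cumulative": "",
            "physical_clones": _sci(sum(_round3(r.physical_clones)
                                        for r in self.rows)),
            "diversity": "",
            "coverage": "",
            "unique_clones": _sci(sum(_round3(r.unique_clones)
                                      for r in self.rows)),
            "avg_duplicates": "",
        })
        return out

    def to_csv(self, path_or_buf=None, formatted: bool = False):
        import pandas as pd

        if formatted:
            df = pd.DataFrame(self.format_rows())
        else:
            df = self.to_dataframe()
        return df.to_csv(path_or_buf, index=False)

    def to_text(self) -> str:
        rows = self.format_rows()
        cols = list(rows[0])
        widths = {c: max(len(c), *(len(r[c]) for r in rows)) for c in cols}
        lines = ["  ".join(c.ljust(widths[c]) for c in cols)]
        for r in rows:
            lines.append("  ".join(r[c].rjust(widths[c]) for c in cols))
        return "\n".join(lines)


def _pct(x: float) -> str:
    if 1.0 - x < 5e-5:
        return "100.00%"
    return f"{100.0 * x:.2f}%"


def _round3(x: float) -> float:
    """Round to 3 significant figures."""
    if x == 0:
        return 0.0
    e = math.floor(math.log10(abs(x)))
    return round(x, 2 - e)


def _sci(x: float) -> str:
    if x == 0:
        return "0"
    if abs(x - 1.0) < 5e-7:
        return "1.00"
    e = math.floor(math.log10(abs(x)))
    mant = x / 10 ** e
    # keep 3 significant figures
    mant = round(mant, 2)
    if mant >= 10:
        mant /= 10
        e += 1
    if 0 <= e < 6 and x < 1e6:
        v = mant * 10 ** e
        return f"{v:.2f}" if e < 4 else f"{mant:.2f}e+{e:02d}"
    return f"{mant:.2f}e+{e:02d}"


def build_design_table(design: DopedDesign) -> DesignTable:
    """Build the full mutation-class table (rows k = 0..m, plus totals).

    Expected clone counts ``n_k`` stay real-valued before any division so
    duplication ratios are reproduced at full precision.
    """
    rows: list[MutationClassRow] = []
    cum = 0.0
    N = design.library_size
    for k in range(design.m + 1):
        frac = mutation_class_fraction(design, k)
        cum += frac
        n_k = N * frac
        D_k = theoretical_diversity(design, k)
        cov = poisson_coverage(n_k, D_k)
        U_k = D_k * cov
        r_k = n_k / U_k if U_k > 0 else float("nan")
        rows.append(MutationClassRow(
            k=k, fraction=frac, cumulative=cum, physical_clones=n_k,
            diversity=D_k, coverage=cov, unique_clones=U_k,
            avg_duplicates=r_k,
        ))
    return DesignTable(design=design, rows=rows)


def pool_complexity(designs: Sequence[DopedDesign]) -> int:
    """Cumulative physical complexity of a pooled set of sub-libraries."""
    designs = list(designs)
    if not designs:
        raise ValueError("need at least one design")
    return sum(d.library_size for d in designs)
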