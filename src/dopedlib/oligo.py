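"""Trimer-codon oligo design for doped libraries.

A doped insert is synthesized with trinucleotide (trimer) phosphoramidite
blocks: each randomized position is an exact mixture of codons, one codon
per allowed residue, with the wild-type codon at the doping weight and the
alternatives sharing the remainder equally.  Fixed positions carry a single
codon.

Because the position-wise codon distribution is known exactly, the
probability that a random library member contains an unwanted restriction
site (NcoI / NotI, needed uniquely for cloning) can be computed *exactly*
by propagating a probability distribution over the states of an
Aho--Corasick automaton built from the recognition sequences — a transfer
-matrix pass linear in sequence length.  A deterministic coordinate-descent
optimizer swaps synonymous codons to drive this probability down.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .design import AMINO_ACIDS, DopedDesign

__all__ = [
    "CodonMixture",
    "OligoSpec",
    "RestrictionSite",
    "NCOI",
    "NOTI",
    "HUMAN_CODON",
    "SENSE_CODONS",
    "build_codon_mixtures",
    "build_oligo_spec",
    "site_probability",
    "enumerate_site_probability",
    "optimize_codons",
    "exhaustive_optimize",
    "assemble_duplex",
    "digest_check",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

#: sense codons per amino acid (standard genetic code, stops excluded)
SENSE_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    SENSE_CODONS.setdefault(_aa, ())
    SENSE_CODONS[_aa] += (_codon,)

#: one codon per amino acid, the highest-usage human codon — the default
#: starting assignment for mixtures and the optimizer.
HUMAN_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

_STOPS = frozenset(standard_dna_table.stop_codons)


def _translate(codon: str) -> str:
    try:
        return standard_dna_table.forward_table[codon]
    except KeyError:
        raise ValueError(f"{codon!r} is a stop codon or invalid") from None


def _check_dna(s: str, what: str) -> None:
    if any(b not in _BASE_IDX for b in s):
        raise ValueError(f"{what} must contain only ACGT, got {s!r}")


def revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class RestrictionSite:
    name: str
    recognition: str

    def __post_init__(self):
        if not self.recognition:
            raise ValueError("recognition sequence must be nonempty")
        _check_dna(self.recognition, "recognition sequence")


NCOI = RestrictionSite("NcoI", "CCATGG")
NOTI = RestrictionSite("NotI", "GCGGCCGC")


@dataclass(frozen=True)
class CodonMixture:
    """An exact per-position codon mixture (one trimer block per residue)."""

    position_label: int
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(
            (c, float(w)) for c, w in self.entries))
        total = 0.0
        residues = set()
        for codon, w in self.entries:
            if len(codon) != 3:
                raise ValueError(f"codon {codon!r} is not a triplet")
            _check_dna(codon, "codon")
            if codon in _STOPS:
                raise ValueError(f"stop codon {codon} not allowed")
            aa = _translate(codon)
            if aa in residues:
                raise ValueError(
                    f"two codons for residue {aa} in one mixture")
            residues.add(aa)
            if w < 0:
                raise ValueError("weights must be nonnegative")
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, not 1")

    @property
    def residues(self) -> frozenset[str]:
        return frozenset(_translate(c) for c, _ in self.entries)


@dataclass(frozen=True)
class OligoSpec:
    """A degenerate oligo: fixed flanks around a body of codons/mixtures."""

    name: str
    five_prime_flank: str
    body: tuple
    three_prime_flank: str

    def __post_init__(self):
        _check_dna(self.five_prime_flank, "5' flank")
        _check_dna(self.three_prime_flank, "3' flank")
        for el in self.body:
            if isinstance(el, str):
                if len(el) != 3:
                    raise ValueError(f"fixed body codon {el!r} not a triplet")
                _check_dna(el, "fixed codon")
            elif not isinstance(el, CodonMixture):
                raise TypeError("body elements must be codons or CodonMixture")
        object.__setattr__(self, "body", tuple(self.body))

    def elements(self):
        """Iterate the spec as fixed strings and mixtures, 5' to 3'."""
        if self.five_prime_flank:
            yield self.five_prime_flank
        yield from self.body
        if self.three_prime_flank:
            yield self.three_prime_flank

    @property
    def n_variable(self) -> int:
        return sum(isinstance(e, CodonMixture) for e in self.body)


# ---------------------------------------------------------------------------
# mixture construction

def build_codon_mixtures(
    design: DopedDesign,
    codon_choice: Mapping[int, Mapping[str, str]] | None = None,
) -> list[CodonMixture]:
    """Per-position trimer mixtures for every randomized position.

    Parent positions get the wt codon at weight ``p_wt`` and each of the
    ``n_alternatives`` non-wt, non-Cys residues at ``(1 - p_wt) / a``.
    N-terminal extension slots (labels < 0) have no wild type and get a
    uniform mixture over the 19 non-Cys residues.

    ``codon_choice`` maps position label -> residue -> codon; omitted
    positions/residues fall back to :data:`HUMAN_CODON`.
    """
    codon_choice = codon_choice or {}
    mixtures = []
    for pos in design.randomized_positions:
        per_pos = codon_choice.get(pos, {})

        def codon_for(aa: str) -> str:
            c = per_pos.get(aa, HUMAN_CODON[aa])
            if _translate(c) != aa:
                raise ValueError(
                    f"codon {c} does not encode {aa} (position {pos})")
            return c

        if "C" in per_pos:
            raise ValueError("Cys is excluded from doped mixtures")
        if pos < 0:
            aas = [a for a in AMINO_ACIDS if a != "C"]
            w = 1.0 / len(aas)
            entries = [(codon_for(a), w) for a in aas]
        else:
            wt = design.parent[pos - 1]
            if wt == "C":
                raise ValueError("cannot dope a Cys parent position")
            alts = [a for a in AMINO_ACIDS if a not in ("C", wt)]
            alts = alts[: design.n_alternatives]
            entries = [(codon_for(wt), design.p_wt)]
            w_alt = (1.0 - design.p_wt) / len(alts)
            entries += [(codon_for(a), w_alt) for a in alts]
        mixtures.append(CodonMixture(position_label=pos, entries=tuple(entries)))
    return mixtures


def build_oligo_spec(
    design: DopedDesign,
    codon_choice: Mapping[int, Mapping[str, str]] | None = None,
    five_prime_flank: str = "",
    three_prime_flank: str = "",
) -> OligoSpec:
    """Full insert spec: fixed wt codons everywhere except the randomized
    positions, which carry doped mixtures."""
    mixtures = {m.position_label: m
                for m in build_codon_mixtures(design, codon_choice)}
    ext = sorted(p for p in design.randomized_positions if p < 0)
    body: list = [mixtures[p] for p in ext]
    for i, aa in enumerate(design.parent, start=1):
        body.append(mixtures.get(i, HUMAN_CODON[aa])
                    if i in mixtures else HUMAN_CODON[aa])
    return OligoSpec(name=design.name or "insert",
                     five_prime_flank=five_prime_flank,
                     body=tuple(body),
                     three_prime_flank=three_prime_flank)


# ---------------------------------------------------------------------------
# exact site probability (Aho--Corasick transfer matrix)

class _SiteAutomaton:
    """DFA over ACGT recognizing any of a set of patterns; matching is an
    absorbing HIT state, so the state distribution after a pass gives the
    exact probability that >= 1 site occurred."""

    def __init__(self, patterns: Sequence[str]):
        patterns = sorted(set(patterns))
        # trie
        goto: list[dict[str, int]] = [{}]
        terminal: list[bool] = [False]
        for pat in patterns:
            s = 0
            for ch in pat:
                if ch not in goto[s]:
                    goto.append({})
                    terminal.append(False)
                    goto[s][ch] = len(goto) - 1
                s = goto[s][ch]
            terminal[s] = True
        n = len(goto)
        fail = [0] * n
        # BFS failure links
        from collections import deque
        queue = deque()
        for ch, s in goto[0].items():
            queue.append(s)
        while queue:
            s = queue.popleft()
            for ch, t in goto[s].items():
                queue.append(t)
                f = fail[s]
                while f and ch not in goto[f]:
                    f = fail[f]
                fail[t] = goto[f].get(ch, 0) if goto[f].get(ch, 0) != t else 0
                terminal[t] = terminal[t] or terminal[fail[t]]
        self.hit = n  # absorbing state index
        delta = np.empty((n + 1, 4), dtype=np.int64)
        for s in range(n):
            for bi, ch in enumerate(_BASES):
                t = s
                while t and ch not in goto[t]:
                    t = fail[t]
                t = goto[t].get(ch, 0)
                delta[s, bi] = self.hit if terminal[t] else t
        delta[self.hit, :] = self.hit
        self.delta = delta
        self.n_states = n + 1
        self._codon_maps: dict[str, np.ndarray] = {}

    def string_map(self, s: str) -> np.ndarray:
        """State map for consuming the fixed string ``s``."""
        m = np.arange(self.n_states)
        for ch in s:
            m = self.delta[m, _BASE_IDX[ch]]
        return m

    def codon_map(self, codon: str) -> np.ndarray:
        m = self._codon_maps.get(codon)
        if m is None:
            m = self.string_map(codon)
            self._codon_maps[codon] = m
        return m

    def element_maps(self, element) -> list[tuple[np.ndarray, float]]:
        if isinstance(element, str):
            return [(self.string_map(element), 1.0)]
        return [(self.codon_map(c), w) for c, w in element.entries]

    def push(self, dist: np.ndarray, element) -> np.ndarray:
        out = np.zeros_like(dist)
        for m, w in self.element_maps(element):
            np.add.at(out, m, w * dist)
        return out

    def pull(self, h: np.ndarray, element) -> np.ndarray:
        """Backward pass: h[s] = P(hit | state s before this suffix)."""
        out = np.zeros_like(h)
        for m, w in self.element_maps(element):
            out += w * h[m]
        return out


def _patterns(sites: Iterable[RestrictionSite], both_strands: bool) -> list[str]:
    pats = [s.recognition for s in sites]
    if not pats:
        raise ValueError("need at least one restriction site")
    if both_strands:
        pats += [revcomp(p) for p in pats]
    return sorted(set(pats))


def site_probability(spec: OligoSpec, sites: Sequence[RestrictionSite],
                     both_strands: bool = False) -> float:
    """Exact probability that a random library member contains >= 1
    occurrence of >= 1 recognition sequence.

    Scanning is on the given (coding) strand by default; NcoI and NotI
    recognition sequences are palindromic, so double-strand scanning is
    redundant for them.  Set ``both_strands`` for non-palindromic enzymes.
    """
    aut = _SiteAutomaton(_patterns(sites, both_strands))
    dist = np.zeros(aut.n_states)
    dist[0] = 1.0
    for el in spec.elements():
        dist = aut.push(dist, el)
    return float(dist[aut.hit])


def enumerate_site_probability(spec: OligoSpec,
                               sites: Sequence[RestrictionSite],
                               both_strands: bool = False,
                               max_combinations: int = 200_000) -> float:
    """Brute-force oracle: enumerate every codon combination.

    Exponential in the number of variable positions — intended for specs
    with <= 3 mixtures in tests.
    """
    pats = _patterns(sites, both_strands)
    choices = []
    for el in spec.elements():
        if isinstance(el, str):
            choices.append([(el, 1.0)])
        else:
            choices.append(list(el.entries))
    n_comb = math.prod(len(c) for c in choices)
    if n_comb > max_combinations:
        raise ValueError(f"{n_comb} combinations exceed the enumeration cap")
    prob = 0.0
    for combo in itertools.product(*choices):
        seq = "".join(c for c, _ in combo)
        w = math.prod(w for _, w in combo)
        if any(p in seq for p in pats):
            prob += w
    return prob


# ---------------------------------------------------------------------------
# codon optimization

def _variable_indices(elements: list) -> list[int]:
    return [i for i, e in enumerate(elements) if isinstance(e, CodonMixture)]


def optimize_codons(
    design: DopedDesign,
    sites: Sequence[RestrictionSite] = (NCOI, NOTI),
    candidates: Mapping[str, Sequence[str]] | None = None,
    codon_choice: Mapping[int, Mapping[str, str]] | None = None,
    five_prime_flank: str = "",
    three_prime_flank: str = "",
    both_strands: bool = False,
    threshold: float | None = None,
    max_sweeps: int = 50,
    optimize_fixed: bool = True,
):
    """Choose one codon per (position, residue) minimizing the site
    probability of the doped insert.

    Deterministic coordinate descent: positions are swept 5'->3'; at each
    position, for each residue, every candidate codon is scored by the
    exact conditional hit probability (forward state distribution x
    backward hit probability) and the best is kept, ties broken by codon
    sort order.  Sweeps repeat until no choice changes.  Because the hit
    probability is linear in each mixture entry, the per-residue choice at
    a position is exactly optimal given the other positions.

    The constant (non-randomized) codons of the insert body are part of
    the synthesis design too, so they are optimized by default as well
    (``optimize_fixed=False`` freezes them); flanks are never touched.

    Returns ``(codon_choice, achieved_probability, feasible)`` where
    ``feasible`` is False when a ``threshold`` was given and not reached
    (reported, not raised).  ``codon_choice`` maps position label ->
    residue -> codon for every optimized body position.
    """
    candidates = {aa: tuple(c) for aa, c in (candidates or SENSE_CODONS).items()}
    for aa, cods in candidates.items():
        if not cods:
            raise ValueError(f"no candidate codons for residue {aa}")
        for c in cods:
            if _translate(c) != aa:
                raise ValueError(f"candidate {c} does not encode {aa}")

    base_spec = build_oligo_spec(design, codon_choice,
                                 five_prime_flank, three_prime_flank)
    aut = _SiteAutomaton(_patterns(sites, both_strands))
    elements = list(base_spec.elements())
    body_lo = 1 if base_spec.five_prime_flank else 0
    body_hi = body_lo + len(base_spec.body)

    # body element index -> position label (extension slots first)
    ext = sorted(p for p in design.randomized_positions if p < 0)
    labels = {body_lo + j: p for j, p in enumerate(ext)}
    for i in range(1, len(design.parent) + 1):
        labels[body_lo + len(ext) + i - 1] = i

    sweep_idx = [i for i in range(body_lo, body_hi)
                 if isinstance(elements[i], CodonMixture)
                 or (optimize_fixed and isinstance(elements[i], str))]

    # position label -> residue -> current codon
    choice: dict[int, dict[str, str]] = {}
    for i in sweep_idx:
        el = elements[i]
        if isinstance(el, CodonMixture):
            choice[labels[i]] = {_translate(c): c for c, _ in el.entries}
        else:
            choice[labels[i]] = {_translate(el): el}

    def rebuild(i: int) -> None:
        el = elements[i]
        per = choice[labels[i]]
        if isinstance(el, CodonMixture):
            elements[i] = CodonMixture(
                position_label=el.position_label,
                entries=tuple((per[_translate(c)], w) for c, w in el.entries))
        else:
            elements[i] = per[_translate(el)]

    for _sweep in range(max_sweeps):
        improved = False
        for i in sweep_idx:
            # forward distribution before element i
            F = np.zeros(aut.n_states)
            F[0] = 1.0
            for el in elements[:i]:
                F = aut.push(F, el)
            # backward hit probability after element i
            H = np.zeros(aut.n_states)
            H[aut.hit] = 1.0
            for el in reversed(elements[i + 1:]):
                H = aut.pull(H, el)
            per = choice[labels[i]]
            for aa in sorted(per):
                pool = candidates.get(aa, (per[aa],))
                best = min(sorted(pool),
                           key=lambda c: float(F @ H[aut.codon_map(c)]))
                if best != per[aa]:
                    per[aa] = best
                    improved = True
            rebuild(i)
        if not improved:
            break

    final_spec = OligoSpec(name=base_spec.name,
                           five_prime_flank=base_spec.five_prime_flank,
                           body=tuple(elements[
                               (1 if base_spec.five_prime_flank else 0):
                               len(elements) - (1 if base_spec.three_prime_flank else 0)]),
                           three_prime_flank=base_spec.three_prime_flank)
    achieved = site_probability(final_spec, sites, both_strands)
    feasible = threshold is None or achieved < threshold
    return choice, achieved, feasible


def exhaustive_optimize(
    spec: OligoSpec,
    sites: Sequence[RestrictionSite],
    candidates: Mapping[str, Sequence[str]],
    both_strands: bool = False,
    max_assignments: int = 200_000,
):
    """Exact optimum by enumerating every codon assignment (toy specs).

    Returns ``(best_assignment, best_probability)`` where the assignment
    maps (position_label, residue) -> codon.
    """
    elements = list(spec.elements())
    var_idx = _variable_indices(elements)
    slots: list[tuple[int, str, tuple[str, ...]]] = []
    for i in var_idx:
        for c, _w in elements[i].entries:
            aa = _translate(c)
            slots.append((i, aa, tuple(sorted(candidates.get(aa, (c,))))))
    n = math.prod(len(s[2]) for s in slots)
    if n > max_assignments:
        raise ValueError(f"{n} assignments exceed the enumeration cap")
    best = None
    for combo in itertools.product(*(s[2] for s in slots)):
        trial = list(elements)
        by_el: dict[int, dict[str, str]] = {}
        for (i, aa, _), codon in zip(slots, combo):
            by_el.setdefault(i, {})[aa] = codon
        for i, per in by_el.items():
            mix = elements[i]
            trial[i] = CodonMixture(
                position_label=mix.position_label,
                entries=tuple((per[_translate(c)], w) for c, w in mix.entries))
        lo = 1 if spec.five_prime_flank else 0
        hi = len(trial) - (1 if spec.three_prime_flank else 0)
        p = site_probability(
            OligoSpec(name=spec.name,
                      five_prime_flank=spec.five_prime_flank,
                      body=tuple(trial[lo:hi]),
                      three_prime_flank=spec.three_prime_flank),
            sites, both_strands)
        key = {(elements[i].position_label, aa): codon
               for (i, aa, _), codon in zip(slots, combo)}
        if best is None or p < best[1]:
            best = (key, p)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# duplex assembly and digestion

@dataclass(frozen=True)
class Duplex:
    sequence: str        # top strand, 5'->3'
    overlap: int         # annealed 3'-3' overlap length
    forward: str
    reverse: str


class AssemblyError(ValueError):
    pass


def assemble_duplex(forward: str, reverse: str, min_overlap: int = 6) -> Duplex:
    """Model primer-extension assembly of two oligos (both given 5'->3').

    The longest 3'-terminal region of the forward strand that is
    complementary to the 3'-terminal region of the reverse strand anneals;
    polymerase extension then yields a full duplex whose top strand is the
    forward oligo followed by the complement of the reverse oligo's
    unannealed 5' portion.
    """
    forward, reverse = forward.upper(), reverse.upper()
    _check_dna(forward, "forward oligo")
    _check_dna(reverse, "reverse oligo")
    max_o = min(len(forward), len(reverse))
    for o in range(max_o, min_overlap - 1, -1):
        if forward[-o:] == revcomp(reverse[-o:]):
            top = forward + revcomp(reverse[: len(reverse) - o])
            return Duplex(sequence=top, overlap=o,
                          forward=forward, reverse=reverse)
    raise AssemblyError(
        f"no complementary 3' overlap of >= {min_overlap} nt found")


def digest_check(duplex: str | Duplex,
                 enzymes: Sequence[RestrictionSite] = (NCOI, NOTI),
                 ) -> tuple[dict[str, list[int]], bool]:
    """Locate every recognition-site occurrence (0-based, top strand) and
    report whether the fragment is clonable: exactly one occurrence of each
    of the first two enzymes, in the given order (NcoI 5' of NotI)."""
    seq = duplex.sequence if isinstance(duplex, Duplex) else duplex.upper()
    _check_dna(seq, "sequence")
    positions: dict[str, list[int]] = {}
    for enz in enzymes:
        hits = []
        start = 0
        while True:
            i = seq.find(enz.recognition, start)
            if i < 0:
                break
            hits.append(i)
            start = i + 1  # overlapping occurrences count
        positions[enz.name] = hits
    clonable = False
    if len(enzymes) >= 2:
        a, b = positions[enzymes[0].name], positions[enzymes[1].name]
        clonable = len(a) == 1 and len(b) == 1 and a[0] < b[0]
    return positions, clonable
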