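"""Sequence-to-feature encoding.

Two bases are supported:

* **onehot** (background-relative): an intercept column (the wild-type
  term), one binary column per observed single substitution, and one binary
  column per substitution combination of order 2..K that co-occurs in at
  least one variant.  An interaction column is, row-wise, the product of its
  constituent single-substitution columns.

* **ensemble** (background-averaged): for biallelic positions this is a
  (rescaled) Walsh-Hadamard embedding; in general each position contributes
  a factor whose "mean" column is 1 for every allele and whose
  mutant-allele-m column is delta(allele, m) - 1/a for a alleles at that
  position.  The multi-position embedding is the row-wise product over the
  chosen positions (Kronecker structure), truncated to terms of order <= K.
  With this scaling, solving the full-order linear system on a complete
  combinatorial landscape yields exactly the background-averaged epistatic
  coefficients: alternating differences averaged over all genetic
  backgrounds, with the order-0 term equal to the landscape mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, prod
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design_io import Substitution, VariantTable


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class Coefficient:
    """Metadata for one feature-matrix column."""

    name: str
    order: int
    subs: tuple[Substitution, ...]
    basis: str  # "onehot" | "ensemble"


@dataclass
class FeatureMatrix:
    """Encoded variants: rows = variants, columns = coefficients."""

    values: np.ndarray
    coefficients: list[Coefficient]
    basis: str

    def __post_init__(self):
        names = [c.name for c in self.coefficients]
        if len(set(names)) != len(names):
            raise EncodingError("coefficient names must be unique")
        if self.values.shape[1] != len(self.coefficients):
            raise EncodingError("column count does not match coefficient metadata")

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficients)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.coefficients]

    @property
    def orders(self) -> np.ndarray:
        return np.array([c.order for c in self.coefficients], dtype=int)

    def metadata_frame(self, trait: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": np.arange(self.n_coefficients),
                "name": self.names,
                "order": self.orders,
                "basis": self.basis,
            }
        )
        if trait is not None:
            df.insert(3, "trait", trait)
        return df


def _interaction_name(subs: Iterable[Substitution]) -> str:
    return ":".join(s.name for s in sorted(subs))


INTERCEPT_NAME = "WT"


# -- onehot basis -------------------------------------------------------------


def observed_onehot_features(
    table: VariantTable, max_interaction_order: int
) -> list[tuple[Substitution, ...]]:
    """Singles plus all co-occurring substitution combinations up to order K."""
    if max_interaction_order < 1:
        raise EncodingError("max_interaction_order must be >= 1")
    singles = [(s,) for s in table.single_substitutions()]
    combos: set[tuple[Substitution, ...]] = set()
    for order in range(2, max_interaction_order + 1):
        for subs in table.subs:
            if len(subs) >= order:
                for c in itertools.combinations(sorted(subs), order):
                    combos.add(c)
    return singles + sorted(combos, key=lambda c: (len(c), _interaction_name(c)))


def encode_onehot(
    table: VariantTable,
    max_interaction_order: int = 1,
    features: Sequence[tuple[Substitution, ...]] | None = None,
    downsample_interactions: int | float | None = None,
    seed: int | np.random.SeedSequence = 0,
    allow_unknown: bool = False,
) -> FeatureMatrix:
    """One-hot encode variants with interaction terms.

    ``features`` overrides automatic enumeration with an explicit coefficient
    list (tuples of substitutions, order >= 1); used both for restricting a
    fit to a subset of terms and for aligning several tables to shared
    columns.  ``downsample_interactions`` randomly retains only a number or
    fraction of the non-intercept columns (uniformly across orders).

    ``allow_unknown=True`` permits features whose substitutions never occur
    in this table (their columns are all zero); used when aligning several
    tables of a shared trait to common columns.
    """
    if features is None:
        feats = observed_onehot_features(table, max_interaction_order)
    else:
        known = set(table.single_substitutions())
        feats = [tuple(sorted(f)) for f in features]
        for f in feats:
            if not f:
                raise EncodingError("explicit features must have order >= 1")
            if not allow_unknown:
                unknown = [s.name for s in f if s not in known]
                if unknown:
                    raise EncodingError(
                        f"explicit feature list contains substitution(s) never "
                        f"observed in this table: {', '.join(unknown)}"
                    )
    if downsample_interactions is not None:
        n_avail = len(feats)
        if isinstance(downsample_interactions, float) and downsample_interactions <= 1.0:
            target = int(round(downsample_interactions * n_avail))
        else:
            target = int(downsample_interactions)
        if target > n_avail:
            raise EncodingError("cannot downsample to more coefficients than exist")
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(n_avail, size=target, replace=False))
        feats = [feats[i] for i in keep]

    n = table.n
    # indicator per single substitution
    single_set = sorted({s for f in feats for s in f})
    col_of = {s: j for j, s in enumerate(single_set)}
    singles_mat = np.zeros((n, len(single_set)), dtype=float)
    for i, subs in enumerate(table.subs):
        for s in subs:
            j = col_of.get(s)
            if j is not None:
                singles_mat[i, j] = 1.0

    values = np.empty((n, 1 + len(feats)), dtype=float)
    values[:, 0] = 1.0
    coeffs = [Coefficient(INTERCEPT_NAME, 0, (), "onehot")]
    for j, f in enumerate(feats, start=1):
        col = singles_mat[:, col_of[f[0]]]
        for s in f[1:]:
            col = col * singles_mat[:, col_of[s]]
        values[:, j] = col
        coeffs.append(Coefficient(_interaction_name(f), len(f), f, "onehot"))
    return FeatureMatrix(values=values, coefficients=coeffs, basis="onehot")


# -- ensemble (background-averaged) basis -------------------------------------


@dataclass
class PositionAlleles:
    """Allele structure of one mutated position: WT symbol + mutant symbols."""

    pos: int
    wt: str
    mutants: tuple[str, ...]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.mutants)


def position_structure(table: VariantTable) -> list[PositionAlleles]:
    """Derive the mutated positions and their allele sets from a table."""
    alleles: dict[int, set[str]] = {}
    for subs in table.subs:
        for s in subs:
            alleles.setdefault(s.pos, set()).add(s.mut)
    if not alleles:
        raise EncodingError(
            "cannot determine position/allele structure: no substitutions observed"
        )
    return [
        PositionAlleles(pos, table.wild_type[pos], tuple(sorted(alleles[pos])))
        for pos in sorted(alleles)
    ]


def ensemble_terms(
    positions: list[PositionAlleles], max_order: int
) -> list[tuple[Substitution, ...]]:
    """All background-averaged terms of order 1..K: a position subset plus a
    chosen mutant allele per position in the subset."""
    terms: list[tuple[Substitution, ...]] = []
    for order in range(1, max_order + 1):
        for pos_subset in itertools.combinations(positions, order):
            for muts in itertools.product(*[p.mutants for p in pos_subset]):
                terms.append(
                    tuple(
                        Substitution(p.pos, p.wt, m)
                        for p, m in zip(pos_subset, muts)
                    )
                )
    terms.sort(key=lambda t: (len(t), _interaction_name(t)))
    return terms


def encode_ensemble(
    table: VariantTable,
    max_interaction_order: int,
    positions: list[PositionAlleles] | None = None,
    features: Sequence[tuple[Substitution, ...]] | None = None,
) -> FeatureMatrix:
    """Embed variants in the background-averaged epistasis basis.

    ``positions`` may be supplied to fix the allele structure externally
    (e.g. the union over several tables); otherwise it is derived from the
    table.  ``features`` restricts the columns to an explicit term list.
    """
    if max_interaction_order < 1:
        raise EncodingError("max_interaction_order must be >= 1")
    if positions is None:
        positions = position_structure(table)
    by_pos = {p.pos: p for p in positions}
    # verify every observed substitution is covered by the declared structure
    for subs in table.subs:
        for s in subs:
            p = by_pos.get(s.pos)
            if p is None or s.mut not in p.mutants:
                raise EncodingError(
                    f"substitution {s.name} not covered by the position/allele structure"
                )
    terms = (
        ensemble_terms(positions, max_interaction_order)
        if features is None
        else [tuple(sorted(f)) for f in features]
    )

    n = table.n
    # per-(position, mutant) centered indicator: delta(allele, m) - 1/a
    w: dict[tuple[int, str], np.ndarray] = {}
    seqs = table.sequences
    for p in positions:
        col = np.array([s[p.pos] for s in seqs])
        a = p.n_alleles
        for m in p.mutants:
            w[(p.pos, m)] = (col == m).astype(float) - 1.0 / a

    values = np.empty((n, 1 + len(terms)), dtype=float)
    values[:, 0] = 1.0
    coeffs = [Coefficient(INTERCEPT_NAME, 0, (), "ensemble")]
    for j, t in enumerate(terms, start=1):
        col = w[(t[0].pos, t[0].mut)]
        for s in t[1:]:
            col = col * w[(s.pos, s.mut)]
        values[:, j] = col
        coeffs.append(Coefficient(_interaction_name(t), len(t), t, "ensemble"))
    return FeatureMatrix(values=values, coefficients=coeffs, basis="ensemble")


def background_averaged_coefficients_bruteforce(
    table: VariantTable, max_order: int | None = None
) -> dict[str, float]:
    """Independent brute-force background-averaged decomposition.

    For every term (a set of substitutions S), the coefficient is the
    inclusion-exclusion alternating difference of phenotype over the 2^|S|
    sub-genotypes of S, averaged over every complete genetic background at
    the remaining positions.  Requires a complete combinatorial landscape.
    Exponential cost -- intended as a test oracle on tiny landscapes.
    """
    positions = position_structure(table)
    if max_order is None:
        max_order = len(positions)
    y_of = {s: y for s, y in zip(table.sequences, table.fitness)}
    expected = prod(p.n_alleles for p in positions)
    if len(y_of) != expected:
        raise EncodingError("brute-force oracle requires a complete landscape")

    def seq_for(assignment: Mapping[int, str]) -> str:
        chars = list(table.wild_type)
        for pos, sym in assignment.items():
            chars[pos] = sym
        return "".join(chars)

    out: dict[str, float] = {INTERCEPT_NAME: float(np.mean(table.fitness))}
    for term in ensemble_terms(positions, max_order):
        term_pos = [s.pos for s in term]
        others = [p for p in positions if p.pos not in term_pos]
        bg_iter = itertools.product(*[[p.wt, *p.mutants] for p in others])
        total = 0.0
        count = 0
        for bg in bg_iter:
            assignment = {p.pos: sym for p, sym in zip(others, bg)}
            diff = 0.0
            for include in itertools.product([False, True], repeat=len(term)):
                a = dict(assignment)
                sign = 1.0
                for s, inc in zip(term, include):
                    a[s.pos] = s.mut if inc else s.wt
                    if not inc:
                        sign = -sign
                diff += sign * y_of[seq_for(a)]
            total += diff
            count += 1
        out[_interaction_name(term)] = total / count
    return out


# -- coefficient counting -----------------------------------------------------


def count_coefficients(
    n_positions_by_allele_count: Mapping[int, int],
    max_order: int,
    basis: str = "onehot",
) -> int:
    """Number of columns (incl. intercept) for a complete combinatorial design.

    ``n_positions_by_allele_count`` maps total alleles per position (WT
    included) to the number of such positions, e.g. ``{2: 13}`` for 13
    biallelic positions.  Both bases share the closed form

        sum_{k=0..K} sum_{k-subsets} prod (alleles - 1).

    Computed via the generating polynomial prod (1 + (a-1) x) truncated at K.
    """
    if max_order < 0:
        raise EncodingError("max_order must be >= 0")
    poly = np.zeros(max_order + 1)
    poly[0] = 1.0
    for alleles, n_pos in n_positions_by_allele_count.items():
        if alleles < 2 or n_pos < 0:
            raise EncodingError("allele counts must be >= 2 and position counts >= 0")
        for _ in range(n_pos):
            shifted = np.zeros_like(poly)
            shifted[1:] = poly[:-1] * (alleles - 1)
            poly = poly + shifted
    return int(round(poly.sum()))
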