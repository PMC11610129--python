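"""Model-design and variant-table input/output.

The model design is a tab-separated table with columns ``trait``,
``transformation``, ``phenotype`` and ``file``; each row declares one
observed phenotype, the additive trait(s) feeding it (comma-separated), the
global-epistasis transformation linking traits to the molecular phenotype,
and the path of the variant table holding the measurements.

Variant tables are tab-separated with a sequence column (``aa_seq`` or
``nt_seq``), a ``fitness`` column (the measured phenotype score) and a
``sigma`` column (its empirical standard error) -- the output dialect of
count-based DMS preprocessors such as DiMSum or Enrich2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .transformations import DEFAULT_REGISTRY, TransformationRegistry

SEQUENCE_COLUMNS = ("aa_seq", "nt_seq")
DESIGN_COLUMNS = ("trait", "transformation", "phenotype", "file")


class DesignError(ValueError):
    """Configuration problem in a model-design table."""


class VariantTableError(ValueError):
    """Malformed variant table."""


# -- substitutions ------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Substitution:
    """A single-position change relative to the wild type (1-based in name)."""

    pos: int  # 0-based position
    wt: str
    mut: str

    @property
    def name(self) -> str:
        return f"{self.wt}{self.pos + 1}{self.mut}"

    def __str__(self) -> str:
        return self.name


def substitutions_between(wild_type: str, seq: str) -> tuple[Substitution, ...]:
    """Position-by-position substitution set of ``seq`` relative to the WT."""
    if len(seq) != len(wild_type):
        raise VariantTableError(
            f"sequence length {len(seq)} differs from wild type {len(wild_type)}"
        )
    return tuple(
        Substitution(i, w, s) for i, (w, s) in enumerate(zip(wild_type, seq)) if w != s
    )


def apply_substitutions(wild_type: str, subs: Iterable[Substitution]) -> str:
    chars = list(wild_type)
    for s in subs:
        if chars[s.pos] != s.wt:
            raise VariantTableError(f"substitution {s.name} does not match wild type")
        chars[s.pos] = s.mut
    return "".join(chars)


# -- model design -------------------------------------------------------------


@dataclass(frozen=True)
class DesignRow:
    phenotype: str
    traits: tuple[str, ...]
    transformation: str
    file: str


@dataclass
class ModelDesign:
    """Validated architecture specification: one row per observed phenotype."""

    rows: list[DesignRow]

    def __post_init__(self):
        if not self.rows:
            raise DesignError("model design must contain at least one row")
        names = [r.phenotype for r in self.rows]
        if len(set(names)) != len(names):
            raise DesignError("phenotype names must be unique across design rows")
        for r in self.rows:
            if not r.traits:
                raise DesignError(f"row {r.phenotype!r} lists no traits")

    @property
    def trait_names(self) -> list[str]:
        """All trait names, in first-appearance order."""
        seen: list[str] = []
        for r in self.rows:
            for t in r.traits:
                if t not in seen:
                    seen.append(t)
        return seen

    def validate_transformations(
        self, registry: TransformationRegistry | None = None
    ) -> None:
        registry = registry or DEFAULT_REGISTRY
        for r in self.rows:
            registry.create(r.transformation, len(r.traits))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": [",".join(r.traits) for r in self.rows],
                "transformation": [r.transformation for r in self.rows],
                "phenotype": [r.phenotype for r in self.rows],
                "file": [r.file for r in self.rows],
            }
        )


def parse_model_design(
    path: str | Path,
    registry: TransformationRegistry | None = None,
    validate: bool = True,
) -> ModelDesign:
    """Read and validate a tab-separated model-design table."""
    path = Path(path)
    if not path.exists():
        raise DesignError(f"model design file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DesignError(f"model design file is empty: {path}") from None
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"model design is missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise DesignError(f"model design has no rows: {path}")
    rows = [
        DesignRow(
            phenotype=str(rec["phenotype"]).strip(),
            traits=tuple(t.strip() for t in str(rec["trait"]).split(",") if t.strip()),
            transformation=str(rec["transformation"]).strip(),
            file=str(rec["file"]).strip(),
        )
        for rec in df.to_dict("records")
    ]
    design = ModelDesign(rows)
    if validate:
        design.validate_transformations(registry)
    return design


def write_model_design(design: ModelDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


# -- variant tables -----------------------------------------------------------


@dataclass
class VariantTable:
    """Sequences with fitness and empirical error, plus derived substitutions.

    ``data`` holds columns seq, fitness, sigma; ``subs`` and
    ``mutation_order`` are aligned lists derived against ``wild_type``.
    """

    data: pd.DataFrame
    wild_type: str
    sequence_column: str = "aa_seq"
    subs: list[tuple[Substitution, ...]] = field(default_factory=list)

    def __post_init__(self):
        if not self.subs:
            self.subs = [
                substitutions_between(self.wild_type, s) for s in self.data["seq"]
            ]
        self.data = self.data.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def sequences(self) -> np.ndarray:
        return self.data["seq"].to_numpy()

    @property
    def fitness(self) -> np.ndarray:
        return self.data["fitness"].to_numpy(dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return self.data["sigma"].to_numpy(dtype=float)

    @property
    def mutation_order(self) -> np.ndarray:
        return np.array([len(s) for s in self.subs], dtype=int)

    @property
    def wild_type_index(self) -> int:
        return int(np.flatnonzero(self.mutation_order == 0)[0])

    def single_substitutions(self) -> list[Substitution]:
        """Sorted unique single substitutions observed anywhere in the table."""
        return sorted({s for subs in self.subs for s in subs})

    def subset(self, idx: Sequence[int]) -> "VariantTable":
        idx = list(idx)
        return VariantTable(
            data=self.data.iloc[idx].reset_index(drop=True),
            wild_type=self.wild_type,
            sequence_column=self.sequence_column,
            subs=[self.subs[i] for i in idx],
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.rename(columns={"seq": self.sequence_column})
        out.to_csv(path, sep="\t", index=False)


def variant_table_from_frame(
    df: pd.DataFrame,
    wild_type: str | None = None,
    sequence_column: str | None = None,
) -> VariantTable:
    """Build a :class:`VariantTable` from an in-memory DiMSum-style frame."""
    if sequence_column is None:
        found = [c for c in SEQUENCE_COLUMNS if c in df.columns]
        if not found:
            raise VariantTableError(
                f"no sequence column; expected one of {SEQUENCE_COLUMNS}"
            )
        sequence_column = found[0]
    for col in (sequence_column, "fitness", "sigma"):
        if col not in df.columns:
            raise VariantTableError(f"variant table is missing column {col!r}")
    data = pd.DataFrame(
        {
            "seq": df[sequence_column].astype(str).str.strip(),
            "fitness": pd.to_numeric(df["fitness"]),
            "sigma": pd.to_numeric(df["sigma"]),
        }
    )
    if len(data) == 0:
        raise VariantTableError("variant table is empty")
    lengths = data["seq"].str.len()
    if lengths.nunique() != 1:
        raise VariantTableError("sequences have unequal lengths")
    if (data["sigma"] <= 0).any():
        raise VariantTableError("sigma must be positive for all variants")
    if data["seq"].duplicated().any():
        dups = data.loc[data["seq"].duplicated(), "seq"].iloc[0]
        raise VariantTableError(
            f"duplicate variant sequence {dups!r}; aggregate replicates upstream"
        )
    if wild_type is None:
        # WT = the unique zero-substitution sequence; without an override the
        # only self-consistent candidate check is done after choosing each
        # sequence as reference, but any sequence is order-0 against itself,
        # so the convention is: the WT must be marked by being present and is
        # taken as the sequence minimizing total Hamming distance only if
        # unique -- in practice fixed-length DMS tables always contain the WT.
        wild_type = _infer_wild_type(data["seq"].tolist())
    wild_type = str(wild_type).strip()
    if len(wild_type) != int(lengths.iloc[0]):
        raise VariantTableError("wild-type length differs from table sequences")
    table = VariantTable(data=data, wild_type=wild_type, sequence_column=sequence_column)
    if not np.any(table.mutation_order == 0):
        raise VariantTableError(
            "wild-type sequence not present in table and no override supplied"
        )
    return table


def _infer_wild_type(seqs: list[str]) -> str:
    """Infer the WT as the sequence with minimal summed Hamming distance.

    For any DMS library built by mutating a reference, the reference is the
    unique sequence closest on average to all others; ties raise.
    """
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    if n == 1:
        return seqs[0]
    totals = np.zeros(n, dtype=int)
    # consensus-based shortcut: compare each sequence to the column-wise modes
    for j in range(arr.shape[1]):
        col = arr[:, j]
        vals, counts = np.unique(col, return_counts=True)
        freq = dict(zip(vals, counts))
        totals += np.array([n - freq[c] for c in col])
    best = np.flatnonzero(totals == totals.min())
    if len(best) > 1:
        cands = sorted(seqs[i] for i in best)
        raise VariantTableError(
            f"wild type is ambiguous (candidates {cands[:3]}...); pass wild_type="
        )
    return seqs[int(best[0])]


def load_variant_table(
    path: str | Path,
    wild_type: str | None = None,
) -> VariantTable:
    """Load a tab-separated variant table (aa_seq|nt_seq, fitness, sigma)."""
    path = Path(path)
    if not path.exists():
        raise VariantTableError(f"variant table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    return variant_table_from_frame(df, wild_type=wild_type)


def filter_and_downsample(
    table: VariantTable,
    order_subset: set[int] | Sequence[int] | None = None,
    downsample_observations: int | float | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> VariantTable:
    """Restrict to given mutation orders and/or randomly downsample.

    The wild type is always retained.  ``downsample_observations`` is either
    an integer target size (including the wild type) or a fraction of the
    available rows.  Deterministic given ``seed``.
    """
    if table.n == 0:
        raise VariantTableError("cannot filter an empty table")
    orders = table.mutation_order
    keep = np.ones(table.n, dtype=bool)
    if order_subset is not None:
        allowed = set(int(o) for o in order_subset)
        keep = np.array([o in allowed for o in orders])
    keep[orders == 0] = True  # WT always retained
    idx = np.flatnonzero(keep)
    if downsample_observations is not None:
        n_avail = len(idx)
        if isinstance(downsample_observations, float) and downsample_observations <= 1.0:
            target = int(round(downsample_observations * n_avail))
        else:
            target = int(downsample_observations)
        if target > n_avail:
            raise VariantTableError(
                f"requested {target} observations but only {n_avail} available"
            )
        if target < 1:
            raise VariantTableError("downsample target must be at least 1")
        rng = np.random.default_rng(seed)
        wt_pos = np.flatnonzero(orders[idx] == 0)
        non_wt = np.delete(idx, wt_pos)
        if len(wt_pos):
            chosen = rng.choice(non_wt, size=target - 1, replace=False)
            idx = np.sort(np.concatenate([[idx[wt_pos[0]]], chosen]))
        else:
            idx = np.sort(rng.choice(idx, size=target, replace=False))
    return table.subset(idx)


# -- joint dataset ------------------------------------------------------------


@dataclass
class JointDataset:
    """Per-phenotype variant tables aligned to the rows of a ModelDesign.

    A union observation index maps each measurement to (phenotype index,
    local row), so multimodal models can be trained on the concatenation.
    """

    design: ModelDesign
    tables: list[VariantTable]

    def __post_init__(self):
        if len(self.tables) != len(self.design.rows):
            raise DesignError("one variant table required per design row")
        self.obs_phenotype = np.concatenate(
            [np.full(t.n, k, dtype=int) for k, t in enumerate(self.tables)]
        )
        self.obs_local = np.concatenate(
            [np.arange(t.n, dtype=int) for t in self.tables]
        )

    @property
    def n_obs(self) -> int:
        return int(len(self.obs_phenotype))

    @property
    def mutation_order(self) -> np.ndarray:
        return np.concatenate([t.mutation_order for t in self.tables])

    @property
    def fitness(self) -> np.ndarray:
        return np.concatenate([t.fitness for t in self.tables])

    @property
    def sigma(self) -> np.ndarray:
        return np.concatenate([t.sigma for t in self.tables])

    def tables_for_trait(self, trait: str) -> list[int]:
        """Design-row indices whose trait list contains ``trait``."""
        return [k for k, r in enumerate(self.design.rows) if trait in r.traits]


def load_joint_dataset(
    design: ModelDesign,
    base_dir: str | Path | None = None,
    wild_type: str | None = None,
) -> JointDataset:
    """Load every variant table referenced by a model design."""
    base = Path(base_dir) if base_dir is not None else None
    tables = []
    for row in design.rows:
        p = Path(row.file)
        if base is not None and not p.is_absolute():
            p = base / p
        if not p.exists():
            raise DesignError(
                f"variant table for phenotype {row.phenotype!r} not found: {p}"
            )
        tables.append(load_variant_table(p, wild_type=wild_type))
    return JointDataset(design=design, tables=tables)
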