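"""Synthetic combinatorial libraries with known ground truth.

Generates complete or sampled combinatorial mutant libraries (biallelic and
multiallelic positions), simulates fitness under a declared genotype-
phenotype model (additive trait coefficients, a global-epistasis
transformation, per-phenotype affine calibration, Gaussian measurement
noise), and scores how well fitted coefficients recover the planted truth.
Every other module is testable against these fixtures without downloading
any real dataset.

The built-in ``scenario_*`` functions define one parameter-recovery setting
per transformation family; their defaults are the package's reference study
conditions (library sizes mirroring published combinatorial designs, noise
at or below 5% of the fitness range).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design_io import (
    DesignRow,
    JointDataset,
    ModelDesign,
    Substitution,
    VariantTable,
    variant_table_from_frame,
)
from .encode import encode_ensemble, encode_onehot, position_structure
from .model_fit import TrainConfig
from .transformations import DEFAULT_REGISTRY


class SyntheticDataError(ValueError):
    pass


# -- library designs ----------------------------------------------------------


@dataclass(frozen=True)
class LibraryDesign:
    """Ordered mutated positions: (wild-type symbol, mutant symbols)."""

    positions: tuple[tuple[str, tuple[str, ...]], ...]

    @property
    def wild_type(self) -> str:
        return "".join(wt for wt, _ in self.positions)

    @property
    def full_size(self) -> int:
        size = 1
        for _, muts in self.positions:
            size *= 1 + len(muts)
        return size

    @classmethod
    def biallelic(cls, n_positions: int, wt: str = "A", mut: str = "V"):
        return cls(tuple((wt, (mut,)) for _ in range(n_positions)))

    @classmethod
    def from_allele_counts(
        cls, counts: Mapping[int, int], alphabet: str = "ACDEFGHIKL"
    ):
        """e.g. {2: 10, 3: 1} -> 10 biallelic + 1 triallelic position."""
        positions = []
        for alleles, n_pos in sorted(counts.items()):
            if alleles < 2 or alleles > len(alphabet):
                raise SyntheticDataError("allele count out of range")
            for _ in range(n_pos):
                positions.append((alphabet[0], tuple(alphabet[1:alleles])))
        return cls(tuple(positions))


def generate_library(
    design: LibraryDesign,
    seed: int | np.random.SeedSequence = 0,
    sample: int | None = None,
) -> list[str]:
    """Enumerate the full factorial library (deterministic order), or draw a
    seeded uniform sample of ``sample`` distinct genotypes (WT included)."""
    alphabets = [(wt, *muts) for wt, muts in design.positions]
    if sample is None:
        return ["".join(combo) for combo in itertools.product(*alphabets)]
    if sample < 1 or sample > design.full_size:
        raise SyntheticDataError(
            f"sample size must be in 1..{design.full_size}"
        )
    rng = np.random.default_rng(seed)
    total = design.full_size
    radices = [len(a) for a in alphabets]
    seqs = {design.wild_type}
    if total < 2**31:
        # enumerable space: sample mixed-radix codes without replacement
        chosen = rng.choice(total, size=sample - 1, replace=False)
        for code in chosen:
            c = int(code)
            chars = []
            for alleles, r in zip(alphabets, radices):
                chars.append(alleles[c % r])
                c //= r
            seqs.add("".join(chars))
    # top up after collisions with WT, or sample a huge space directly
    while len(seqs) < sample:
        draw = rng.integers(0, radices)
        seqs.add("".join(a[i] for a, i in zip(alphabets, draw)))
    return sorted(seqs)


# -- ground truth and simulation ----------------------------------------------


@dataclass
class GroundTruth:
    """Planted generative model for a scenario.

    ``trait_coefs`` maps trait -> {coefficient name: value}; the order-0
    wild-type term is stored under "WT".  ``phenotypes`` lists, per observed
    phenotype, the traits used, the transformation name with its true
    parameters, and the affine calibration.  ``basis`` selects the additive
    encoding the truth is expressed in.
    """

    trait_coefs: dict
    phenotypes: list  # dicts: name, traits, transformation, params, scale, shift
    noise_sd: float
    basis: str = "onehot"
    max_order: int = 1

    def coefficient_frame(self) -> pd.DataFrame:
        recs = []
        for trait, coefs in self.trait_coefs.items():
            for name, value in coefs.items():
                order = 0 if name == "WT" else name.count(":") + 1
                recs.append(
                    {"trait": trait, "name": name, "order": order, "true_value": value}
                )
        return pd.DataFrame(recs)


def _trait_phi(table: VariantTable, coefs: Mapping[str, float], basis: str, max_order: int):
    """Additive trait values for every variant under the planted coefficients."""
    if basis == "ensemble":
        fm = encode_ensemble(table, max_order)
    else:
        fm = encode_onehot(table, max_order)
    theta = np.array([coefs.get(name, 0.0) for name in fm.names])
    unknown = set(coefs) - set(fm.names)
    if unknown:
        raise SyntheticDataError(f"truth names not encodable: {sorted(unknown)[:5]}")
    return fm.values @ theta


def simulate_fitness(
    sequences: Sequence[str] | Mapping[str, Sequence[str]],
    wild_type: str,
    truth: GroundTruth,
    seed: int | np.random.SeedSequence = 0,
) -> JointDataset:
    """Simulate measured fitness for every phenotype of a ground truth.

    ``sequences`` is either one list shared by all phenotypes or a mapping
    phenotype name -> list.  y = scale * g(phi) + shift + Normal(0, sd^2);
    the sigma column holds the true noise sd, so the empirical noise model
    is well-specified (a dummy 1e-6 is used when sd = 0).
    """
    root = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    noise_seeds = root.spawn(len(truth.phenotypes))
    rows = []
    tables = []
    for ph, child in zip(truth.phenotypes, noise_seeds):
        seqs = (
            sequences[ph["name"]] if isinstance(sequences, Mapping) else sequences
        )
        base = variant_table_from_frame(
            pd.DataFrame({"aa_seq": seqs, "fitness": 0.0, "sigma": 1.0}),
            wild_type=wild_type,
        )
        phi = np.stack(
            [
                _trait_phi(base, truth.trait_coefs[t], truth.basis, truth.max_order)
                for t in ph["traits"]
            ],
            axis=1,
        )
        transform = DEFAULT_REGISTRY.create(ph["transformation"], len(ph["traits"]))
        p = transform.forward(phi, ph.get("params", {}))
        y = ph["scale"] * p + ph["shift"]
        rng = np.random.default_rng(child)
        sd = truth.noise_sd
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=len(y))
        sigma = sd if sd > 0 else 1e-6
        table = variant_table_from_frame(
            pd.DataFrame({"aa_seq": seqs, "fitness": y, "sigma": sigma}),
            wild_type=wild_type,
        )
        tables.append(table)
        rows.append(
            DesignRow(
                phenotype=ph["name"],
                traits=tuple(ph["traits"]),
                transformation=ph["transformation"],
                file=f"{ph['name']}.tsv",
            )
        )
    return JointDataset(design=ModelDesign(rows), tables=tables)


# -- recovery scoring ---------------------------------------------------------


def score_recovery(
    truth: GroundTruth,
    estimates: pd.DataFrame,
    value_column: str = "theta_mean",
    orientation: float = 1.0,
) -> dict:
    """Compare fitted coefficients to the planted truth.

    Alignment is by (trait, name); order-0 terms are excluded so the score
    is gauge-free (only energy *differences* are compared).  ``orientation``
    (+1/-1) pre-multiplies the estimates, for learned transformations whose
    trait sign is a gauge mode.  Returns Pearson r, RMSE, the number of
    matched coefficients, unmatched names, and (when interval columns are
    present) the fraction of truths covered by the 95% intervals.
    """
    tf = truth.coefficient_frame()
    tf = tf[tf["order"] > 0]
    est = estimates[estimates["name"] != "WT"].copy()
    est["_value"] = orientation * est[value_column]
    merged = tf.merge(est, on=["trait", "name"], how="left")
    unmatched = merged.loc[merged["_value"].isna(), "name"].tolist()
    ok = merged.dropna(subset=["_value"])
    if len(ok) < 2:
        raise SyntheticDataError("fewer than two matched coefficients")
    t = ok["true_value"].to_numpy(dtype=float)
    e = ok["_value"].to_numpy(dtype=float)
    r = float(stats.pearsonr(t, e).statistic) if np.std(t) > 0 and np.std(e) > 0 else np.nan
    out = {
        "pearson_r": r,
        "rmse": float(np.sqrt(np.mean((t - e) ** 2))),
        "n_matched": int(len(ok)),
        "unmatched": unmatched,
    }
    if {"ci95_lower", "ci95_upper"} <= set(estimates.columns):
        lo = orientation * ok["ci95_lower"].to_numpy(dtype=float)
        hi = orientation * ok["ci95_upper"].to_numpy(dtype=float)
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
        width = hi - lo
        covered = (t >= lo) & (t <= hi)
        # zero-width intervals (identical models) cover only exact equality;
        # guard the degenerate all-zero-width case explicitly
        out["ci_coverage"] = float(np.mean(covered)) if np.any(width > 0) else np.nan
    return out


def fitted_trait_orientation(model, phenotype: int = 0) -> float:
    """+1 if the fitted phenotype increases with the (first) additive trait.

    Determined from the fitted model alone (slope sign of predictions vs
    trait), so learned global-epistasis fits can be gauge-aligned to a
    generating model of known monotone direction without peeking at truth
    coefficients.
    """
    phi = model.phi(phenotype)[:, 0]
    y_hat = model.predict_row(phenotype)
    if np.std(phi) == 0:
        return 1.0
    slope = np.polyfit(phi, y_hat, 1)[0]
    return 1.0 if slope >= 0 else -1.0


# -- built-in scenarios -------------------------------------------------------


@dataclass
class Scenario:
    name: str
    dataset: JointDataset
    truth: GroundTruth
    seed: int
    train_config: TrainConfig = field(
        # small combinatorial libraries: smaller batches give Adam enough
        # steps per epoch to traverse the slow affine-vs-trait directions
        default_factory=lambda: TrainConfig(batch_size=128)
    )


def _sub_names(design: LibraryDesign) -> list[str]:
    names = []
    for i, (wt, muts) in enumerate(design.positions):
        for m in muts:
            names.append(Substitution(i, wt, m).name)
    return names


def _noise_from_range(y: np.ndarray, fraction: float) -> float:
    return float(fraction * np.ptp(y))


def _build(
    name: str,
    design: LibraryDesign,
    truth_builder,
    seed: int,
    sample: int | None = None,
    noise_fraction: float = 0.05,
) -> Scenario:
    root = np.random.SeedSequence(seed)
    coef_seed, lib_seed, noise_seed = root.spawn(3)
    rng = np.random.default_rng(coef_seed)
    truth = truth_builder(rng)
    seqs = generate_library(design, seed=lib_seed, sample=sample)
    # calibrate the noise sd to the stated fraction of the noiseless range
    silent = GroundTruth(
        trait_coefs=truth.trait_coefs,
        phenotypes=truth.phenotypes,
        noise_sd=0.0,
        basis=truth.basis,
        max_order=truth.max_order,
    )
    clean = simulate_fitness(seqs, design.wild_type, silent, seed=noise_seed)
    sd = max(
        _noise_from_range(t.fitness, noise_fraction) for t in clean.tables
    )
    truth.noise_sd = sd
    dataset = simulate_fitness(seqs, design.wild_type, truth, seed=noise_seed)
    return Scenario(name=name, dataset=dataset, truth=truth, seed=seed)


def scenario_linear(seed: int = 0) -> Scenario:
    """Purely additive landscape, identity transformation.

    40 biallelic positions, 2000 sampled genotypes, coefficients N(0, 0.5),
    noise at 5% of the fitness range.
    """
    design = LibraryDesign.biallelic(40)
    names = _sub_names(design)

    def build(rng):
        coefs = {"WT": 0.3, **{n: v for n, v in zip(names, rng.normal(0, 0.5, len(names)))}}
        return GroundTruth(
            trait_coefs={"Trait": coefs},
            phenotypes=[
                {
                    "name": "assay",
                    "traits": ["Trait"],
                    "transformation": "Linear",
                    "scale": 1.0,
                    "shift": 0.0,
                }
            ],
            noise_sd=0.0,
        )

    return _build("linear", design, build, seed, sample=2000)


def scenario_two_state(seed: int = 0) -> Scenario:
    """Two-state folding equilibrium: 10 biallelic positions, complete
    1024-variant landscape; a stable wild type (dG0 = -2.5 RT) destabilized
    by mostly positive ddG ~ N(0.6, 0.5); fraction folded read out through
    an affine assay calibration; noise 5% of range."""
    design = LibraryDesign.biallelic(10)
    names = _sub_names(design)

    def build(rng):
        coefs = {"WT": -2.5, **{n: v for n, v in zip(names, rng.normal(0.6, 0.5, len(names)))}}
        return GroundTruth(
            trait_coefs={"Folding": coefs},
            phenotypes=[
                {
                    "name": "aPCA",
                    "traits": ["Folding"],
                    "transformation": "TwoStateFractionFolded",
                    "scale": 1.4,
                    "shift": -0.2,
                }
            ],
            noise_sd=0.0,
        )

    return _build("two_state", design, build, seed)


def scenario_three_state(seed: int = 0) -> Scenario:
    """Multimodal ddPCA-style design: a shared folding energy read out by an
    abundance assay (two-state) and, jointly with a binding energy, by a
    binding assay (three-state).  9 biallelic positions, complete 512-variant
    landscape measured in both assays."""
    design = LibraryDesign.biallelic(9)
    names = _sub_names(design)

    def build(rng):
        fold = {"WT": -1.5, **{n: v for n, v in zip(names, rng.normal(0.5, 0.5, len(names)))}}
        bind = {"WT": -1.0, **{n: v for n, v in zip(names, rng.normal(0.4, 0.6, len(names)))}}
        return GroundTruth(
            trait_coefs={"Folding": fold, "Binding": bind},
            phenotypes=[
                {
                    "name": "aPCA",
                    "traits": ["Folding"],
                    "transformation": "TwoStateFractionFolded",
                    "scale": 1.2,
                    "shift": -0.1,
                },
                {
                    "name": "bPCA",
                    "traits": ["Folding", "Binding"],
                    "transformation": "ThreeStateFractionBound",
                    "scale": 1.0,
                    "shift": 0.0,
                },
            ],
            noise_sd=0.0,
        )

    return _build("three_state", design, build, seed)


def scenario_splicing(seed: int = 0) -> Scenario:
    """Splice-site competition: 10 biallelic + 1 triallelic position
    (2^10 x 3 = 3072 exon variants), multiplicative mutation effects on
    splicing efficiency, trainable competing-exon parameter k7."""
    design = LibraryDesign.from_allele_counts({2: 10, 3: 1}, alphabet="ACGT")
    names = _sub_names(design)

    def build(rng):
        coefs = {"WT": 1.0, **{n: v for n, v in zip(names, rng.normal(0.0, 1.2, len(names)))}}
        return GroundTruth(
            trait_coefs={"Inclusion": coefs},
            phenotypes=[
                {
                    "name": "splicing",
                    "traits": ["Inclusion"],
                    "transformation": "SplicingCompetition",
                    "params": {"log_k7": np.array([np.log(1.5)])},
                    "scale": 0.8,
                    "shift": 0.2,
                }
            ],
            noise_sd=0.0,
        )

    return _build("splicing", design, build, seed)


def scenario_sum_of_sigmoids(seed: int = 0) -> Scenario:
    """Unidimensional global epistasis of unknown (to the fit) shape: the
    generating nonlinearity is a logistic saturation; the fit learns it with
    a sum-of-sigmoids sub-network.  12 biallelic positions, 3000 of 4096
    genotypes sampled."""
    design = LibraryDesign.biallelic(12)
    names = _sub_names(design)

    def build(rng):
        coefs = {"WT": -0.5, **{n: v for n, v in zip(names, rng.normal(0.0, 1.2, len(names)))}}
        return GroundTruth(
            trait_coefs={"Trait": coefs},
            phenotypes=[
                {
                    "name": "assay",
                    "traits": ["Trait"],
                    "transformation": "Sigmoid",
                    "scale": 1.3,
                    "shift": -0.2,
                }
            ],
            noise_sd=0.0,
        )

    return _build("sum_of_sigmoids", design, build, seed, sample=3000)


def scenario_sparse_ensemble(
    seed: int = 0, n_positions: int = 13, n_nonzero: int = 20
) -> Scenario:
    """Sparse background-averaged landscape: 13 biallelic positions (8192
    variants), 20 planted nonzero ensemble coefficients spread over orders
    1-4 with well-separated magnitudes (|value| in [0.8, 2]), low noise
    (2% of range)."""
    design = LibraryDesign.biallelic(n_positions)
    root = np.random.SeedSequence(seed)
    coef_seed, _, _ = root.spawn(3)
    rng = np.random.default_rng(coef_seed)

    # enumerate term names from a complete table's position structure
    positions = [
        (i, wt, muts[0]) for i, (wt, muts) in enumerate(design.positions)
    ]
    if n_nonzero == 20:
        per_order = {1: 8, 2: 7, 3: 4, 4: 1}
    else:  # spread planted terms over orders 1..4 for smaller scenarios
        per_order = {}
        for i in range(n_nonzero):
            order = 1 + (i % min(4, n_positions))
            per_order[order] = per_order.get(order, 0) + 1
    chosen: list[str] = []
    for order, count in per_order.items():
        combos = list(itertools.combinations(positions, order))
        picks = rng.choice(len(combos), size=count, replace=False)
        for p in picks:
            term = combos[int(p)]
            chosen.append(
                ":".join(Substitution(i, wt, m).name for i, wt, m in term)
            )
    values = rng.uniform(0.8, 2.0, size=n_nonzero) * rng.choice([-1.0, 1.0], n_nonzero)

    def build(rng_inner):
        coefs = {"WT": 0.5, **dict(zip(chosen, values))}
        return GroundTruth(
            trait_coefs={"Brightness": coefs},
            phenotypes=[
                {
                    "name": "brightness",
                    "traits": ["Brightness"],
                    "transformation": "Linear",
                    "scale": 1.0,
                    "shift": 0.0,
                }
            ],
            noise_sd=0.0,
            basis="ensemble",
            max_order=max(per_order),
        )

    return _build("sparse_ensemble", design, build, seed, noise_fraction=0.02)


SCENARIOS = {
    "linear": scenario_linear,
    "two_state": scenario_two_state,
    "three_state": scenario_three_state,
    "splicing": scenario_splicing,
    "sum_of_sigmoids": scenario_sum_of_sigmoids,
    "sparse_ensemble": scenario_sparse_ensemble,
}


# -- reference recovery studies ----------------------------------------------


def scenario_coverage(seed: int = 0, n_positions: int = 200, n_sample: int = 3000) -> Scenario:
    """Interval-calibration study: a purely additive landscape with 200
    single-substitution coefficients, 3000 sampled genotypes and noise at 5%
    of the fitness range; the well-specified Gaussian likelihood is used so
    interval coverage reflects the Monte-Carlo procedure itself."""
    design = LibraryDesign.biallelic(n_positions)
    names = _sub_names(design)

    def build(rng):
        coefs = {
            "WT": 0.3,
            **{n: v for n, v in zip(names, rng.normal(0, 0.5, len(names)))},
        }
        return GroundTruth(
            trait_coefs={"Trait": coefs},
            phenotypes=[
                {
                    "name": "assay",
                    "traits": ["Trait"],
                    "transformation": "Linear",
                    "scale": 1.0,
                    "shift": 0.0,
                }
            ],
            noise_sd=0.0,
        )

    scenario = _build("coverage", design, build, seed, sample=n_sample)
    scenario.train_config = TrainConfig(
        batch_size=256,
        loss_function_name="GaussianNLL",
        early_stopping=False,
        num_epochs=300,
    )
    return scenario


def run_recovery(name: str, seed: int = 0, task_seed: int | None = None) -> dict:
    """Fit one built-in scenario with its reference training conditions
    (10-fold cross-validation, no grid search) and score coefficient
    recovery against the planted truth."""
    from .project import monte_carlo_intervals, run_task

    scenario = (
        scenario_coverage(seed) if name == "coverage" else SCENARIOS[name](seed=seed)
    )
    if task_seed is None:
        task_seed = seed + 1
    collection = run_task(
        scenario.dataset, config=scenario.train_config, seed=task_seed
    )
    estimates = monte_carlo_intervals(collection)
    out = score_recovery(scenario.truth, estimates)
    out["scenario"] = scenario
    out["collection"] = collection
    out["estimates"] = estimates
    return out


def run_sparse_recovery(seed: int = 0, task_seed: int | None = None, top_n: int = 20) -> dict:
    """Run the two-stage sparse ensemble workflow on the planted-truth
    landscape and count how many planted coefficients rank in the top
    ``top_n`` by magnitude."""
    from .project import sparse_workflow

    scenario = SCENARIOS["sparse_ensemble"](seed=seed)
    if task_seed is None:
        task_seed = seed + 1
    result = sparse_workflow(
        scenario.dataset,
        max_order=6,
        l1_grid=(0.1, 0.01, 0.001),
        top_k=100,
        config=scenario.train_config,
        seed=task_seed,
    )
    planted = {n for n in scenario.truth.trait_coefs["Brightness"] if n != "WT"}
    top = set(result.ranking["name"].head(top_n))
    return {
        "n_planted": len(planted),
        "n_recovered_top": len(planted & top),
        "scenario": scenario,
        "workflow": result,
    }


def write_scenario(scenario: Scenario, out_dir: str | Path) -> Path:
    """Write design_io-compatible variant tables, the model design file and
    the ground-truth coefficient table for a scenario."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for row, table in zip(scenario.dataset.design.rows, scenario.dataset.tables):
        table.to_tsv(out_dir / row.file)
    scenario.dataset.design.to_frame().to_csv(
        out_dir / "model_design.tsv", sep="\t", index=False
    )
    tf = scenario.truth.coefficient_frame()
    tf["noise_sd"] = scenario.truth.noise_sd
    tf["seed"] = scenario.seed
    tf.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False)
    with open(out_dir / "wild_type.txt", "w") as fh:
        fh.write(scenario.dataset.tables[0].wild_type + "\n")
    return out_dir
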