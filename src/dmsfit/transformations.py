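"""Global-epistasis transformations.

A transformation ``g`` maps one or more additive traits (latent phenotypes,
typically free energies in units of RT) to a molecular phenotype, e.g. the
fraction of molecules folded or bound at thermodynamic equilibrium.  This
module provides:

* fixed (parameter-free) thermodynamic forms derived from the Boltzmann
  distribution: two-state and three-state equilibria;
* simple activations (Linear, ReLU, SiLU, Sigmoid);
* ``SumOfSigmoids`` -- a small feed-forward sub-network used to *learn* the
  shape of global epistasis directly from data (uni- or multidimensional);
* ``SplicingCompetition`` -- a mechanistic splice-site competition model with
  one trainable global parameter;
* a plug-in loader so users can register custom transformations from a
  python script at runtime.

Every transformation exposes ``forward`` and ``backward`` so the training
loop can backpropagate through it.  Plug-ins without analytic gradients fall
back to finite differences.
"""

from __future__ import annotations

import importlib.util
import math
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

# -- thermodynamic constants -------------------------------------------------

#: Gas constant in kcal K^-1 mol^-1.
GAS_CONSTANT_KCAL = 0.001987

#: Default assay temperature in Kelvin (30 degrees Celsius).
DEFAULT_TEMPERATURE_K = 303.0


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a temperature given in degrees Celsius to Kelvin (nearest K)."""
    return t_celsius + 273.0


class TransformationError(ValueError):
    """Raised for arity mismatches or malformed plug-ins."""


# -- base class ---------------------------------------------------------------


class Transformation:
    """Base class for global-epistasis functions.

    Subclasses define ``name``, ``n_traits`` (``None`` = any input
    dimensionality) and implement :meth:`forward`.  Trainable parameters live
    in a plain dict of numpy arrays created by :meth:`init_params`; fixed
    transformations return an empty dict.

    ``bounded01`` declares that the output lies in [0, 1]; the model
    assembler uses it to initialize the downstream affine calibration from
    the observed fitness range.
    """

    name: str = "Transformation"
    n_traits: int | None = None
    bounded01: bool = False

    def init_params(self, n_traits: int, rng: np.random.Generator) -> dict:
        return {}

    def forward(self, phi: np.ndarray, params: dict) -> np.ndarray:
        """Evaluate g. ``phi`` has shape (n, n_traits); returns shape (n,)."""
        raise NotImplementedError

    def backward(self, phi: np.ndarray, params: dict, dp: np.ndarray):
        """Return (dL/dphi, dL/dparams) given upstream gradient dp = dL/dg.

        Default implementation uses central finite differences; analytic
        subclasses override it.
        """
        eps = 1e-6
        n, m = phi.shape
        dphi = np.empty_like(phi)
        for j in range(m):
            hi = phi.copy()
            lo = phi.copy()
            hi[:, j] += eps
            lo[:, j] -= eps
            dg = (self.forward(hi, params) - self.forward(lo, params)) / (2 * eps)
            dphi[:, j] = dp * dg
        dparams = {}
        for key, arr in params.items():
            grad = np.empty_like(arr)
            flat = arr.ravel()
            gflat = grad.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                hi = self.forward(phi, params)
                flat[i] = orig - eps
                lo = self.forward(phi, params)
                flat[i] = orig
                gflat[i] = np.sum(dp * (hi - lo) / (2 * eps))
            dparams[key] = grad
        return dphi, dparams

    def _check_arity(self, phi: np.ndarray) -> None:
        if self.n_traits is not None and phi.shape[1] != self.n_traits:
            raise TransformationError(
                f"{self.name} expects {self.n_traits} trait(s), got {phi.shape[1]}"
            )


# -- simple activations -------------------------------------------------------


class Linear(Transformation):
    """Identity map: no global epistasis, g(phi) = phi."""

    name = "Linear"
    n_traits = 1

    def forward(self, phi, params):
        self._check_arity(phi)
        return phi[:, 0].copy()

    def backward(self, phi, params, dp):
        return dp[:, None].copy(), {}


class ReLU(Transformation):
    name = "ReLU"
    n_traits = 1

    def forward(self, phi, params):
        self._check_arity(phi)
        return np.maximum(phi[:, 0], 0.0)

    def backward(self, phi, params, dp):
        return (dp * (phi[:, 0] > 0))[:, None], {}


class SiLU(Transformation):
    """x * sigmoid(x); smooth monotone-ish activation."""

    name = "SiLU"
    n_traits = 1

    def forward(self, phi, params):
        self._check_arity(phi)
        x = phi[:, 0]
        return x * expit(x)

    def backward(self, phi, params, dp):
        x = phi[:, 0]
        s = expit(x)
        return (dp * (s + x * s * (1 - s)))[:, None], {}


class Sigmoid(Transformation):
    """Logistic activation 1/(1+e^-x); increasing, bounded in (0, 1)."""

    name = "Sigmoid"
    n_traits = 1
    bounded01 = True

    def forward(self, phi, params):
        self._check_arity(phi)
        return expit(phi[:, 0])

    def backward(self, phi, params, dp):
        p = expit(phi[:, 0])
        return (dp * p * (1 - p))[:, None], {}


# -- thermodynamic forms ------------------------------------------------------


class TwoStateFractionFolded(Transformation):
    """Fraction of molecules in the low-energy state of a two-state
    equilibrium.

    With the reference state at zero free energy and the alternative state at
    dG (in RT units), the Boltzmann distribution gives the occupied fraction

        p = e^{-dG} / (1 + e^{-dG}) = 1 / (1 + e^{dG}),

    strictly decreasing in dG.  Used both for fraction folded (abundance
    assays) and fraction bound in fold-upon-bind two-state systems.
    """

    name = "TwoStateFractionFolded"
    n_traits = 1
    bounded01 = True

    def forward(self, phi, params):
        self._check_arity(phi)
        return expit(-phi[:, 0])

    def backward(self, phi, params, dp):
        p = expit(-phi[:, 0])
        return (-dp * p * (1 - p))[:, None], {}


class ThreeStateFractionBound(Transformation):
    """Fraction bound in a three-state unfolded/folded/bound equilibrium.

    States and free energies (RT units): unfolded 0, folded dG_f, folded+bound
    dG_f + dG_b.  Boltzmann weights give

        p = e^{-(dG_f+dG_b)} / (1 + e^{-dG_f} + e^{-(dG_f+dG_b)}).

    Traits are ordered (dG_f, dG_b).  Numerically stable via log-sum-exp.
    """

    name = "ThreeStateFractionBound"
    n_traits = 2
    bounded01 = True

    @staticmethod
    def _state_probs(phi):
        # state energies: 0, f, f+b  -> probabilities via logsumexp
        f = phi[:, 0]
        b = phi[:, 1]
        energies = np.stack([np.zeros_like(f), f, f + b], axis=1)
        neg = -energies
        mx = neg.max(axis=1, keepdims=True)
        w = np.exp(neg - mx)
        z = w.sum(axis=1, keepdims=True)
        return w / z  # columns: unfolded, folded, bound

    def forward(self, phi, params):
        self._check_arity(phi)
        return self._state_probs(phi)[:, 2]

    def backward(self, phi, params, dp):
        probs = self._state_probs(phi)
        p_u, p_b = probs[:, 0], probs[:, 2]
        # d p_b / d dG_f = -p_b * p_u ; d p_b / d dG_b = -p_b (1 - p_b)
        dphi = np.stack([-dp * p_b * p_u, -dp * p_b * (1 - p_b)], axis=1)
        return dphi, {}


class SplicingCompetition(Transformation):
    """Splice-site competition model for exon inclusion.

    Inclusion fitness is proportional to log(PSI) where PSI, the fraction of
    transcripts including the exon, arises from two splicing reactions with
    efficiencies k6 (the modeled exon, fixed at 1) and k7 (the competing
    exon, a trainable global parameter).  Mutations act multiplicatively on
    k6, so with the additive trait phi entering as e^phi:

        g(phi) = log( e^phi / (k7 + e^phi) ) = -softplus(log k7 - phi).

    Strictly increasing in phi with upper bound 0.  Positivity of k7 is
    guaranteed by training kappa = log k7.
    """

    name = "SplicingCompetition"
    n_traits = 1

    def init_params(self, n_traits, rng):
        return {"log_k7": np.zeros(1)}

    def forward(self, phi, params):
        self._check_arity(phi)
        kappa = params["log_k7"][0]
        return -np.logaddexp(0.0, kappa - phi[:, 0])

    def backward(self, phi, params, dp):
        kappa = params["log_k7"][0]
        s = expit(kappa - phi[:, 0])  # d(-softplus(u))/du = -sigmoid(u), u = kappa-phi
        dphi = (dp * s)[:, None]
        dkappa = np.array([-np.sum(dp * s)])
        return dphi, {"log_k7": dkappa}


# -- learned global epistasis -------------------------------------------------


class SumOfSigmoids(Transformation):
    """Learned global-epistasis surface: a small sigmoidal sub-network.

    Architecture: input layer of width = trait dimensionality, hidden layers
    (default one layer of 20 neurons), output layer of one neuron.  Every
    layer applies an affine map followed by the logistic activation
    out = 1/(1+e^-in); the output activation can be disabled
    (``output_linear=True``) to yield an unbounded surface.
    """

    name = "SumOfSigmoids"
    n_traits = None  # any dimensionality

    def __init__(self, architecture: Sequence[int] = (20,), output_linear: bool = False):
        if len(architecture) == 0:
            raise TransformationError("SumOfSigmoids needs at least one hidden layer")
        self.architecture = tuple(int(w) for w in architecture)
        if any(w < 1 for w in self.architecture):
            raise TransformationError("hidden layer widths must be positive")
        self.output_linear = bool(output_linear)
        self.bounded01 = not self.output_linear

    def _sizes(self, n_traits):
        return [n_traits, *self.architecture, 1]

    def init_params(self, n_traits, rng):
        sizes = self._sizes(n_traits)
        params = {}
        for i, (fin, fout) in enumerate(zip(sizes[:-1], sizes[1:])):
            bound = math.sqrt(6.0 / (fin + fout))  # Glorot-uniform weights
            params[f"W{i}"] = rng.uniform(-bound, bound, size=(fin, fout))
            params[f"b{i}"] = rng.uniform(-1.0, 1.0, size=fout)
        return params

    def _n_layers(self, params):
        return len(params) // 2

    def forward(self, phi, params, _cache=None):
        a = phi
        n_layers = self._n_layers(params)
        for i in range(n_layers):
            z = a @ params[f"W{i}"] + params[f"b{i}"]
            last = i == n_layers - 1
            a_next = z if (last and self.output_linear) else expit(z)
            if _cache is not None:
                _cache.append((a, a_next))
            a = a_next
        return a[:, 0]

    def backward(self, phi, params, dp):
        cache: list = []
        self.forward(phi, params, _cache=cache)
        n_layers = self._n_layers(params)
        dparams = {}
        da = dp[:, None]
        for i in range(n_layers - 1, -1, -1):
            a_in, a_out = cache[i]
            if i == n_layers - 1 and self.output_linear:
                dz = da
            else:
                dz = da * a_out * (1 - a_out)
            dparams[f"W{i}"] = a_in.T @ dz
            dparams[f"b{i}"] = dz.sum(axis=0)
            da = dz @ params[f"W{i}"].T
        return da, dparams


# -- convenience wrappers matching the field's closed forms -------------------


def two_state_fraction_folded(dg) -> np.ndarray | float:
    """Occupied fraction 1/(1+e^{dG}) for a two-state equilibrium (dG in RT)."""
    return expit(-np.asarray(dg, dtype=float))


def three_state_fraction_bound(dg_f, dg_b) -> np.ndarray | float:
    """Fraction bound for the unfolded/folded/bound three-state equilibrium."""
    scalar = np.isscalar(dg_f) and np.isscalar(dg_b)
    f = np.atleast_1d(np.asarray(dg_f, dtype=float))
    b = np.atleast_1d(np.asarray(dg_b, dtype=float))
    f, b = np.broadcast_arrays(f, b)
    phi = np.stack([f.ravel(), b.ravel()], axis=1)
    out = ThreeStateFractionBound().forward(phi, {}).reshape(f.shape)
    return float(out[0]) if scalar else out


def sum_of_sigmoids(phi, params, architecture=(20,), output_linear=False):
    """Feed-forward evaluation of the SumOfSigmoids sub-network."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    return SumOfSigmoids(architecture, output_linear).forward(phi, params)


def splicing_competition(phi, k7: float) -> np.ndarray | float:
    """log(e^phi / (k7 + e^phi)); k7 > 0."""
    if k7 <= 0:
        raise TransformationError("k7 must be positive")
    phi = np.asarray(phi, dtype=float)
    out = -np.logaddexp(0.0, math.log(k7) - phi)
    return out if out.shape else float(out)


# -- registry and plug-ins ----------------------------------------------------

_BUILTINS: dict[str, Callable[..., Transformation]] = {
    "Linear": Linear,
    "ReLU": ReLU,
    "SiLU": SiLU,
    "Sigmoid": Sigmoid,
    "TwoStateFractionFolded": TwoStateFractionFolded,
    "ThreeStateFractionBound": ThreeStateFractionBound,
    "SplicingCompetition": SplicingCompetition,
    "SumOfSigmoids": SumOfSigmoids,
}


class TransformationRegistry:
    """Name -> transformation factory mapping, extensible by plug-ins."""

    def __init__(self):
        self._factories = dict(_BUILTINS)

    def names(self) -> list[str]:
        return sorted(self._factories)

    def __contains__(self, name: str) -> bool:
        return name in self._factories

    def register(self, name: str, factory: Callable[..., Transformation]) -> None:
        self._factories[name] = factory

    def create(
        self,
        name: str,
        n_traits: int,
        *,
        sos_architecture: Sequence[int] = (20,),
        sos_outputlinear: bool = False,
    ) -> Transformation:
        if name not in self._factories:
            raise TransformationError(
                f"unknown transformation {name!r}; registered: {', '.join(self.names())}"
            )
        factory = self._factories[name]
        if factory is SumOfSigmoids:
            t = SumOfSigmoids(sos_architecture, sos_outputlinear)
        else:
            t = factory() if isinstance(factory, type) else factory()
        if t.n_traits is not None and t.n_traits != n_traits:
            raise TransformationError(
                f"transformation {name!r} takes {t.n_traits} trait(s), "
                f"but the model design row lists {n_traits}"
            )
        if t.n_traits is None:
            t = _bind_arity(t, n_traits)
        return t


def _bind_arity(t: Transformation, n_traits: int) -> Transformation:
    t.n_traits = n_traits
    return t


class _PluginTransformation(Transformation):
    """Wraps a dict-style plug-in (evaluate callable + parameter inits)."""

    def __init__(self, name, n_traits, parameters, evaluate, bounded01=False):
        self.name = name
        self.n_traits = int(n_traits) if n_traits is not None else None
        self._param_init = {
            k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in (parameters or {}).items()
        }
        self._evaluate = evaluate
        self.bounded01 = bounded01

    def init_params(self, n_traits, rng):
        return {k: v.copy() for k, v in self._param_init.items()}

    def forward(self, phi, params):
        self._check_arity(phi)
        out = np.asarray(self._evaluate(phi, params), dtype=float)
        if out.shape != (phi.shape[0],):
            raise TransformationError(
                f"plug-in {self.name!r} evaluate must return shape (n,), got {out.shape}"
            )
        return out


def register_custom_transformations(
    plugin_path: str, registry: TransformationRegistry
) -> list[str]:
    """Load custom transformations from a user python script.

    The script must expose ``TRANSFORMATIONS``: a list whose elements are
    either ``Transformation`` subclasses/instances or dicts with keys
    ``name``, ``n_traits``, ``parameters`` (mapping of parameter name to
    initial value, may be empty) and ``evaluate`` (callable
    ``(phi, params) -> (n,) array``).  Returns the registered names.
    """
    spec = importlib.util.spec_from_file_location("dmsfit_plugin", plugin_path)
    if spec is None or spec.loader is None:
        raise TransformationError(f"cannot load plug-in script {plugin_path!r}")
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    entries = getattr(module, "TRANSFORMATIONS", None)
    if not isinstance(entries, (list, tuple)) or not entries:
        raise TransformationError(
            "plug-in must define a non-empty list TRANSFORMATIONS; each entry is a "
            "Transformation subclass/instance or a dict with keys name, n_traits, "
            "parameters, evaluate"
        )
    names = []
    for entry in entries:
        if isinstance(entry, type) and issubclass(entry, Transformation):
            t = entry()
            registry.register(t.name, entry)
            names.append(t.name)
        elif isinstance(entry, Transformation):
            registry.register(entry.name, lambda e=entry: e)
            names.append(entry.name)
        elif isinstance(entry, dict):
            missing = {"name", "n_traits", "evaluate"} - set(entry)
            if missing:
                raise TransformationError(
                    f"plug-in dict entry missing keys {sorted(missing)}; required "
                    "contract: name, n_traits, parameters (optional), evaluate"
                )
            t = _PluginTransformation(
                entry["name"],
                entry["n_traits"],
                entry.get("parameters"),
                entry["evaluate"],
                bounded01=bool(entry.get("bounded01", False)),
            )
            registry.register(t.name, lambda t=t: t)
            names.append(t.name)
        else:
            raise TransformationError(f"unsupported plug-in entry type: {type(entry)!r}")
    return names


DEFAULT_REGISTRY = TransformationRegistry()
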