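"""Ensemble population kinetics.

Population time series from trajectory ensembles, hop-count matrices, a
first-order mass-action rate-network model (``KineticModel``) with a
least-squares :meth:`KineticModel.fit`, a single-exponential lifetime model
for a spin manifold (``ExponentialDecayModel``), and mean first-hop times.

The default rate network is the six-species, nine-rate scheme used to
describe sequential relaxation with back-transfer in the five-state
photodynamics: main forward S2->S1->T2->T1, the corresponding three
backward steps, and three minority channels (S2->S1', S1'->S0, S2->T2).
The S1' species separates trajectories that will decay to the ground state
from those that undergo intersystem crossing; observably it is reported
inside S1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares


# ---------------------------------------------------------------------------
# population series
# ---------------------------------------------------------------------------

@dataclass
class PopulationSeries:
    """Per-label population fractions on a time grid.

    data : DataFrame indexed by time (fs) with one column per state label;
        rows sum to 1.
    basis : "diagonal_active", "mch_active" or "quantum_amplitude"
    n_traj : ensemble size behind the series (None for model output)
    """

    data: pd.DataFrame
    basis: str
    n_traj: int | None = None

    @property
    def times(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def labels(self) -> list:
        return list(self.data.columns)

    def manifold_sum(self, labels) -> np.ndarray:
        return self.data[list(labels)].sum(axis=1).to_numpy()

    def check_conservation(self, tol=1e-12) -> bool:
        return bool(np.all(np.abs(self.data.sum(axis=1) - 1.0) < tol))

    def to_tsv(self, path, header_lines=()):
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.data.rename_axis("time_fs").to_csv(fh, sep="\t")


def _strip_sublevel(label: str) -> str:
    return label.split("(")[0]


def compute_populations(ensemble, basis: str, grid) -> PopulationSeries:
    """Ensemble population fractions on a time grid.

    ``diagonal_active`` / ``mch_active``: fraction of trajectories whose
    active state carries each label; ``quantum_amplitude``: ensemble mean of
    the electronic populations |c_k|^2 (MCH basis, sublevels merged).
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    grid = np.asarray(grid, dtype=float)
    short = [i for i, tr in enumerate(ensemble) if tr.times[-1] < grid[-1] - 1e-9]
    if short:
        raise ValueError(f"trajectories shorter than the grid: {short}")

    model = ensemble[0].model
    if basis == "diagonal_active":
        labels = [f"D{k}" for k in range(model.nstates)]
        counts = np.zeros((len(grid), len(labels)))
        for tr in ensemble:
            for j, k in enumerate(tr.label_at_times(grid, basis="diag")):
                counts[j, k] += 1
        frac = counts / len(ensemble)
    elif basis == "mch_active":
        labels = model.state_labels
        idx = {lb: i for i, lb in enumerate(labels)}
        counts = np.zeros((len(grid), len(labels)))
        for tr in ensemble:
            for j, lb in enumerate(tr.label_at_times(grid, basis="mch")):
                counts[j, idx[_strip_sublevel(lb)]] += 1
        frac = counts / len(ensemble)
    elif basis == "quantum_amplitude":
        labels = model.state_labels
        idx = {lb: i for i, lb in enumerate(labels)}
        frac = np.zeros((len(grid), len(labels)))
        for tr in ensemble:
            rows = np.clip(np.searchsorted(tr.times, grid, side="right") - 1,
                           0, len(tr) - 1)
            pops = tr.amplitude_populations("mch")[rows]
            for k, lb in enumerate(model.expanded_labels):
                frac[:, idx[_strip_sublevel(lb)]] += pops[:, k]
        frac /= len(ensemble)
    else:
        raise ValueError(f"unknown basis {basis!r}")

    df = pd.DataFrame(frac, index=pd.Index(grid, name="time_fs"), columns=labels)
    return PopulationSeries(data=df, basis=basis, n_traj=len(ensemble))


# ---------------------------------------------------------------------------
# hop matrix
# ---------------------------------------------------------------------------

@dataclass
class HopMatrix:
    """Counts of non-frustrated surface hops between labeled states.

    The stored matrix is never filtered; the rendered report suppresses
    entries below ``report_threshold`` and can bold a main-pathway set.
    """

    counts: pd.DataFrame
    report_threshold: int = 10

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def render(self, main_pathway=(), threshold=None) -> str:
        thr = self.report_threshold if threshold is None else threshold
        main = set(main_pathway)
        lines = ["from\\to\t" + "\t".join(self.counts.columns)]
        for a in self.counts.index:
            row = [a]
            for b in self.counts.columns:
                v = int(self.counts.loc[a, b])
                if a == b or v < thr:
                    row.append(".")
                elif (a, b) in main:
                    row.append(f"**{v}**")
                else:
                    row.append(str(v))
            lines.append("\t".join(row))
        return "\n".join(lines)


def count_hops(ensemble, label_basis: str = "mch",
               report_threshold: int = 10) -> HopMatrix:
    """Tally non-frustrated hops across the ensemble into a from x to matrix."""
    if label_basis == "mch":
        labels = ensemble[0].model.state_labels if ensemble else []
    elif label_basis == "diag":
        labels = [f"D{k}" for k in range(ensemble[0].model.nstates)] if ensemble else []
    else:
        raise ValueError(f"unknown label basis {label_basis!r}")
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for tr in ensemble:
        for h in tr.hops:
            if h.frustrated:
                continue
            if label_basis == "mch":
                a, b = _strip_sublevel(h.from_state), _strip_sublevel(h.to_state)
            else:
                a, b = f"D{h.from_diag}", f"D{h.to_diag}"
            counts.loc[a, b] += 1
    return HopMatrix(counts=counts, report_threshold=report_threshold)


# ---------------------------------------------------------------------------
# kinetic rate-network model
# ---------------------------------------------------------------------------

DEFAULT_SPECIES = ["S0", "S1", "S1p", "S2", "T1", "T2"]
DEFAULT_REACTIONS = [
    # main forward
    ("S2", "S1"), ("S1", "T2"), ("T2", "T1"),
    # main backward
    ("S1", "S2"), ("T2", "S1"), ("T1", "T2"),
    # minority forward
    ("S2", "S1p"), ("S1p", "S0"), ("S2", "T2"),
]
# observable label -> latent species summed into it
DEFAULT_OBSERVABLE_MAP = {"S0": ["S0"], "S1": ["S1", "S1p"],
                          "S2": ["S2"], "T1": ["T1"], "T2": ["T2"]}


class KineticModel:
    """First-order mass-action reaction network dP/dt = K(k) P.

    Parameters
    ----------
    species : ordered latent species labels
    reactions : list of (source, destination) pairs; one rate constant per
        reaction, in fs^-1
    initial_populations : dict label -> fraction (must sum to 1)
    rates : optional dict/sequence of rate constants attached to the model
        (needed for :meth:`simulate` without explicit rates)
    observable_map : observable label -> list of latent species; defaults to
        identity except that S1' is reported inside S1
    """

    def __init__(self, species=None, reactions=None, initial_populations=None,
                 rates=None, observable_map=None):
        self.species = list(species or DEFAULT_SPECIES)
        self.reactions = [tuple(r) for r in (reactions or DEFAULT_REACTIONS)]
        for src, dst in self.reactions:
            if src not in self.species or dst not in self.species:
                raise ValueError(f"reaction {src}->{dst} names unknown species")
        if initial_populations is None:
            initial_populations = {"S2": 1.0}
        p0 = np.zeros(len(self.species))
        for lb, v in initial_populations.items():
            p0[self.species.index(lb)] = v
        if abs(p0.sum() - 1.0) > 1e-9:
            raise ValueError("initial populations must sum to 1")
        self.p0 = p0
        if observable_map is None:
            observable_map = {}
            for sp in self.species:
                if sp == "S1p":
                    continue
                observable_map[sp] = ["S1", "S1p"] if sp == "S1" else [sp]
        self.observable_map = observable_map
        self.rates = None if rates is None else self._coerce_rates(rates)

    def _coerce_rates(self, rates):
        if isinstance(rates, dict):
            k = np.array([rates[f"{a}->{b}"] for a, b in self.reactions])
        else:
            k = np.asarray(rates, dtype=float)
        if k.shape != (len(self.reactions),):
            raise ValueError("one rate constant per reaction required")
        if np.any(k < 0):
            raise ValueError("rate constants must be non-negative")
        return k

    @property
    def rate_names(self):
        return [f"{a}->{b}" for a, b in self.reactions]

    def rate_matrix(self, rates) -> np.ndarray:
        k = self._coerce_rates(rates)
        n = len(self.species)
        K = np.zeros((n, n))
        for (src, dst), kk in zip(self.reactions, k):
            i, j = self.species.index(src), self.species.index(dst)
            K[j, i] += kk
            K[i, i] -= kk
        return K

    def simulate(self, grid, rates=None, observable=True) -> PopulationSeries:
        """Solve the linear ODE system on the grid via matrix exponentials.

        Uniform grids use one expm and repeated stepping; arbitrary grids
        fall back to one expm per time point.  Population is conserved
        exactly by the mass-action structure.
        """
        k = self._coerce_rates(self.rates if rates is None else rates)
        grid = np.asarray(grid, dtype=float)
        K = self.rate_matrix(k)
        P = np.empty((len(grid), len(self.species)))
        dts = np.diff(grid)
        if len(grid) > 1 and np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12) \
                and abs(grid[0]) < 1e-12:
            M = expm(K * dts[0])
            p = self.p0.copy()
            P[0] = p
            for i in range(1, len(grid)):
                p = M @ p
                P[i] = p
        else:
            for i, t in enumerate(grid):
                P[i] = expm(K * t) @ self.p0
        if observable:
            cols = {}
            for obs, members in self.observable_map.items():
                cols[obs] = sum(P[:, self.species.index(m)] for m in members)
            df = pd.DataFrame(cols, index=pd.Index(grid, name="time_fs"))
        else:
            df = pd.DataFrame(P, index=pd.Index(grid, name="time_fs"),
                              columns=self.species)
        return PopulationSeries(data=df, basis="kinetic_model", n_traj=None)

    # -- fitting ---------------------------------------------------------
    def fit(self, data: PopulationSeries, n_starts: int = 10, seed: int = 0,
            bounds=(0.0, 1.0), x0_range=(1e-5, 1e-1),
            ridge: float = 1e-6) -> "KineticFitResult":
        """Nonnegative-bounded least squares over all observable species.

        Multi-start local optimization (log-uniform initial guesses in
        ``x0_range`` fs^-1, seeds logged) against the unweighted sum of
        squared deviations on the data's own grid; returns the best start.

        ``ridge`` adds a negligible penalty ``ridge * k`` per rate to the
        residual vector.  Rates out of species that never acquire population
        are observationally unidentifiable; the penalty selects the
        smallest-rate representative without biasing identifiable rates
        (the penalty's contribution is ~1e-12 of a typical squared error).
        """
        obs_labels = [lb for lb in self.observable_map if lb in data.labels]
        if len(obs_labels) < 2:
            raise ValueError("data must cover at least two species")
        grid = data.times
        y = data.data[obs_labels].to_numpy()

        def residual(k):
            sim = self.simulate(grid, rates=k)
            r = (sim.data[obs_labels].to_numpy() - y).ravel()
            return np.concatenate([r, ridge * np.asarray(k)])

        rng = np.random.default_rng(seed)
        lo, hi = np.log10(x0_range[0]), np.log10(x0_range[1])
        nk = len(self.reactions)
        starts = 10.0 ** rng.uniform(lo, hi, size=(n_starts, nk))
        best = None
        logs = []
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(residual, x0, bounds=bounds,
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                    max_nfev=4000)
            except Exception as exc:  # pragma: no cover - defensive
                logs.append(f"start {i}: failed ({exc})")
                continue
            sse = float(np.sum(sol.fun[:-nk] ** 2))  # data part only
            logs.append(f"start {i}: sse={sse:.3e} status={sol.status}")
            if best is None or sse < best[0]:
                best = (sse, sol)
        if best is None:
            return KineticFitResult(model=self, rates=None, residual=np.inf,
                                    model_populations=None, converged=False,
                                    diagnostics=logs, seed=seed)
        sse, sol = best
        rates = sol.x.copy()

        # identifiability pruning: a rate out of a species that never
        # acquires population leaves the observables untouched; zero those
        # so the reported network is the minimal equivalent one
        def data_sse(k):
            sim = self.simulate(grid, rates=k)
            return float(np.sum((sim.data[obs_labels].to_numpy() - y) ** 2))

        for i in range(len(rates)):
            if rates[i] == 0.0:
                continue
            trial = rates.copy()
            trial[i] = 0.0
            if data_sse(trial) <= sse + 1e-12 * (1.0 + sse):
                rates = trial
                logs.append(f"rate {self.rate_names[i]} unidentifiable; "
                            "pruned to 0")
        sse = data_sse(rates)
        return KineticFitResult(
            model=self, rates=pd.Series(rates, index=self.rate_names),
            residual=sse,
            model_populations=self.simulate(grid, rates=rates),
            converged=bool(sol.status > 0), diagnostics=logs, seed=seed)


@dataclass
class KineticFitResult:
    """Fitted rate constants and diagnostics of a :class:`KineticModel` fit."""

    model: KineticModel
    rates: pd.Series | None
    residual: float
    model_populations: PopulationSeries | None
    converged: bool
    diagnostics: list = field(default_factory=list)
    seed: int = 0
    conf_int: pd.DataFrame | None = None

    @property
    def parameters(self) -> pd.Series:
        return self.rates

    def bootstrap(self, ensemble, grid, basis="mch_active", n_boot=200,
                  seed=0, n_starts=1):
        """Trajectory-level bootstrap confidence intervals (2.5/97.5%).

        Resamples trajectories with replacement, recomputes populations and
        refits (warm-started near the point estimate).
        """
        rng = np.random.default_rng(seed)
        samples = []
        x0 = self.rates.to_numpy()
        obs_labels = [lb for lb in self.model.observable_map]
        for _ in range(n_boot):
            idx = rng.integers(0, len(ensemble), len(ensemble))
            pops = compute_populations([ensemble[i] for i in idx], basis, grid)
            y = pops.data[[lb for lb in obs_labels if lb in pops.labels]].to_numpy()
            lbs = [lb for lb in obs_labels if lb in pops.labels]

            def residual(k):
                sim = self.model.simulate(grid, rates=k)
                return (sim.data[lbs].to_numpy() - y).ravel()

            sol = least_squares(residual, np.clip(x0, 1e-8, 1.0),
                                bounds=(0.0, 1.0), xtol=1e-10, ftol=1e-10,
                                max_nfev=1000)
            samples.append(sol.x)
        arr = np.asarray(samples)
        self.conf_int = pd.DataFrame(
            {"lower": np.percentile(arr, 2.5, axis=0),
             "upper": np.percentile(arr, 97.5, axis=0)},
            index=self.model.rate_names)
        return self.conf_int

    def summary(self) -> str:
        lines = ["Kinetic rate-network fit",
                 f"  converged: {self.converged}   SSE: {self.residual:.6e}",
                 f"  multi-start seed: {self.seed}",
                 "  rate constant (fs^-1)      estimate        2.5%       97.5%"]
        if self.rates is not None:
            for name, v in self.rates.items():
                if self.conf_int is not None:
                    lo = self.conf_int.loc[name, "lower"]
                    hi = self.conf_int.loc[name, "upper"]
                    lines.append(f"  {name:<22s} {v:12.6e} {lo:11.4e} {hi:11.4e}")
                else:
                    lines.append(f"  {name:<22s} {v:12.6e}")
        return "\n".join(lines)


def simulate_kinetics(model: KineticModel, grid) -> PopulationSeries:
    """Functional wrapper: solve the model's rate equations on the grid."""
    return model.simulate(grid)


def fit_kinetic_model(data: PopulationSeries, network: KineticModel | None = None,
                      **options) -> KineticFitResult:
    """Functional wrapper around :meth:`KineticModel.fit`."""
    model = network or KineticModel()
    return model.fit(data, **options)


# ---------------------------------------------------------------------------
# exponential manifold lifetime
# ---------------------------------------------------------------------------

class ExponentialDecayModel:
    """Single-exponential survival model P(t) = exp(-t/tau) for the summed
    population of a spin manifold."""

    def __init__(self, manifold=("S0", "S1", "S2")):
        self.manifold = list(manifold)

    def fit(self, data: PopulationSeries, ensemble=None, grid=None,
            basis="mch_active", n_boot=200, seed=0) -> "ExponentialFitResult":
        missing = [lb for lb in self.manifold if lb not in data.labels]
        if missing:
            raise ValueError(f"manifold labels absent from data: {missing}")
        t = data.times
        y = data.manifold_sum(self.manifold)
        tau, converged = _fit_exp_tau(t, y)
        se = None
        if converged and ensemble is not None:
            g = data.times if grid is None else np.asarray(grid)
            rng = np.random.default_rng(seed)
            taus = []
            for _ in range(n_boot):
                idx = rng.integers(0, len(ensemble), len(ensemble))
                pops = compute_populations([ensemble[i] for i in idx], basis, g)
                tb, ok = _fit_exp_tau(g, pops.manifold_sum(self.manifold))
                if ok:
                    taus.append(tb)
            if taus:
                se = float(np.std(taus, ddof=1))
        return ExponentialFitResult(
            manifold=self.manifold, tau=tau if converged else None,
            tau_se=se, converged=converged,
            residual=float(np.sum((np.exp(-t / tau) - y) ** 2)) if converged else np.inf,
            data=data)


def _fit_exp_tau(t, y):
    """Least-squares tau for P(t) = exp(-t/tau); (tau, converged)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    # a non-decaying series has no finite positive lifetime
    if y[-1] >= y[0] - 1e-12 or np.all(y >= 1.0 - 1e-12):
        return np.nan, False
    pos = (y > 1e-12) & (t > 0)
    if pos.sum() >= 2:
        tau0 = -1.0 / np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        if not np.isfinite(tau0) or tau0 <= 0:
            tau0 = t[-1]
    else:
        tau0 = t[-1]

    def resid(x):
        return np.exp(-t / x[0]) - y

    sol = least_squares(resid, [tau0], bounds=([1e-12], [np.inf]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    return float(sol.x[0]), bool(sol.status > 0)


@dataclass
class ExponentialFitResult:
    manifold: list
    tau: float | None          # fs
    tau_se: float | None       # bootstrap standard error (fs)
    converged: bool
    residual: float
    data: PopulationSeries

    @property
    def parameters(self) -> pd.Series:
        return pd.Series({"tau_fs": self.tau, "tau_se_fs": self.tau_se})

    def summary(self) -> str:
        lines = [f"Exponential manifold decay fit ({'+'.join(self.manifold)})",
                 f"  converged: {self.converged}"]
        if self.converged:
            se = f" +/- {self.tau_se:.1f}" if self.tau_se is not None else ""
            lines.append(f"  lifetime tau = {self.tau:.1f}{se} fs")
            lines.append(f"  SSE = {self.residual:.6e}")
        return "\n".join(lines)


def fit_exponential_manifold(data: PopulationSeries, manifold,
                             **kwargs) -> ExponentialFitResult:
    """Functional wrapper around :meth:`ExponentialDecayModel.fit`."""
    return ExponentialDecayModel(manifold).fit(data, **kwargs)


# ---------------------------------------------------------------------------
# first-hop statistics
# ---------------------------------------------------------------------------

@dataclass
class MeanFirstHopTime:
    from_label: str
    to_label: str
    mean_fs: float | None
    n: int
    n_excluded: int

    @property
    def defined(self) -> bool:
        return self.n > 0


def mean_first_hop_time(ensemble, from_label: str, to_label: str) -> MeanFirstHopTime:
    """Mean time of the first from->to hop over the trajectories showing one.

    Trajectories without such a hop are excluded; their count is reported.
    An ensemble with no qualifying trajectory yields an undefined (flagged)
    result rather than an error.
    """
    times = []
    for tr in ensemble:
        t = tr.first_hop_time(from_label, to_label)
        if t is not None:
            times.append(t)
    n = len(times)
    return MeanFirstHopTime(
        from_label=from_label, to_label=to_label,
        mean_fs=float(np.mean(times)) if n else None,
        n=n, n_excluded=len(ensemble) - n)
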