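"""Markov state model estimation from discrete state trajectories.

The model object (:class:`MarkovStateModel`) is built from per-trajectory
state sequences and a lag time; ``fit()`` returns a :class:`TransitionModel`
results object carrying the transition matrix, the maximum-likelihood
equilibrium populations, the eigenvalue spectrum and validation diagnostics.

Two estimators are provided:

``naive``
    row-normalised counts, ``P_ij = C_ij / Σ_j C_ij``; the stationary
    distribution is the leading left eigenvector.

``reversible-mle``
    maximises the multinomial likelihood subject to detailed balance
    (``π_i P_ij = π_j P_ji``) by the standard self-consistent fixed-point
    iteration on the symmetrised counts; guarantees a real eigenvalue
    spectrum and a strictly positive stationary distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CountMatrix",
    "TransitionModel",
    "ImpliedTimescaleSpectrum",
    "MarkovStateModel",
    "count_transitions",
    "ergodic_trim",
    "estimate_transition_matrix",
    "implied_timescales",
    "rank_states",
]


@dataclass
class CountMatrix:
    """Observed transition counts C_ij at lag τ."""

    counts: np.ndarray
    lag_ns: float
    sliding: bool
    n_states: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.n_states, self.n_states):
            raise ValueError("count matrix must be K x K")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_text(self, path: str | Path, mode: str = "") -> None:
        """Coordinate-format sparse text with a JSON header line."""
        import json

        header = json.dumps({"lag_ns": self.lag_ns, "K": self.n_states, "mode": mode, "sliding": self.sliding})
        lines = ["# " + header]
        ii, jj = np.nonzero(self.counts)
        for i, j in zip(ii, jj):
            lines.append(f"{i} {j} {self.counts[i, j]:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "CountMatrix":
        import json

        lines = Path(path).read_text().splitlines()
        meta = json.loads(lines[0].lstrip("# "))
        counts = np.zeros((meta["K"], meta["K"]))
        for ln in lines[1:]:
            if not ln.strip():
                continue
            i, j, v = ln.split()
            counts[int(i), int(j)] = float(v)
        return cls(counts, meta["lag_ns"], meta.get("sliding", True), meta["K"])


def count_transitions(
    dtrajs: Sequence[np.ndarray],
    lag_ns: float,
    spacing_ns: float,
    n_states: int | None = None,
    sliding: bool = True,
) -> CountMatrix:
    """Count i→j transitions at lag ``lag_ns`` within each trajectory.

    The lag must be a positive integer multiple of the frame spacing;
    trajectories are counted independently (no cross-trajectory pairs).
    Sliding-window mode counts every pair ``(t, t+τ)``; otherwise only
    non-overlapping pairs ``(0, τ), (τ, 2τ), ...`` are counted.
    """
    ratio = lag_ns / spacing_ns
    lag_frames = int(round(ratio))
    if lag_frames < 1 or abs(ratio - lag_frames) > 1e-9 * max(1.0, ratio):
        raise ValueError(
            f"lag {lag_ns} ns must be a positive integer multiple of the frame spacing {spacing_ns} ns"
        )
    if n_states is None:
        n_states = int(max((int(d.max()) for d in dtrajs if len(d)), default=-1)) + 1
    counts = np.zeros((n_states, n_states))
    for d in dtrajs:
        d = np.asarray(d, dtype=int)
        if len(d) <= lag_frames:
            continue
        if sliding:
            src, dst = d[:-lag_frames], d[lag_frames:]
        else:
            sub = d[::lag_frames]
            src, dst = sub[:-1], sub[1:]
        np.add.at(counts, (src, dst), 1)
    return CountMatrix(counts, lag_ns, sliding, n_states)


def ergodic_trim(count_matrix: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Restrict the counts to the largest strongly connected component.

    Returns the trimmed counts and the index map from retained-state index
    to original state index.  A well-defined stationary distribution only
    exists on a strongly connected (ergodic) state set.
    """
    c = count_matrix.counts
    if not c.any():
        raise ValueError("all-zero count matrix: no ergodic component")
    graph = scipy.sparse.csr_matrix((c > 0).astype(np.int8))
    n_comp, comp = connected_components(graph, directed=True, connection="strong")
    # largest component by member count, ties by total counts then lowest index
    best, best_key = None, None
    for k in range(n_comp):
        members = np.flatnonzero(comp == k)
        total = c[np.ix_(members, members)].sum()
        if total == 0 and members.size == 1 and c[members[0], members[0]] == 0:
            # isolated state never observed returning to itself
            if c[members[0]].sum() == 0 and c[:, members[0]].sum() == 0:
                continue
        key = (members.size, total, -members[0])
        if best_key is None or key > best_key:
            best, best_key = members, key
    if best is None or c[np.ix_(best, best)].sum() == 0:
        raise ValueError("largest strongly connected component carries no counts")
    if best.size == 1:
        warnings.warn("ergodic component is a single state; the model is degenerate", stacklevel=2)
    trimmed = CountMatrix(c[np.ix_(best, best)], count_matrix.lag_ns, count_matrix.sliding, best.size)
    return trimmed, best


def _stationary_from_eig(p: np.ndarray) -> np.ndarray:
    vals, vecs = scipy.linalg.eig(p.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _reversible_mle(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent fixed point for the detailed-balanced MLE.

    Iterates ``x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j)`` on the symmetric
    auxiliary variables ``x`` (``c_i`` row sums of C, ``x_i`` row sums of x)
    until the normalised x changes by less than ``tol`` per element.
    """
    c = counts.astype(float)
    csym = c + c.T
    crow = c.sum(axis=1)
    if (crow == 0).any():
        raise ValueError("zero row in trimmed count matrix")
    x = csym.copy()
    x /= x.sum()
    mask = csym > 0
    for _ in range(max_iter):
        xrow = x.sum(axis=1)
        denom = crow[:, None] / xrow[:, None] + crow[None, :] / xrow[None, :]
        x_new = np.where(mask, csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        # convergence on the largest-element scale: the normalised x entries
        # shrink like 1/K^2, so an absolute criterion would over-iterate
        delta = np.abs(x_new - x).max() / x_new.max()
        x = x_new
        if delta < tol:
            break
    else:
        # thin count matrices approach the fixed point with a power-law tail;
        # a residual far below statistical resolution is accepted with a note
        if delta < 1e-6:
            warnings.warn(
                f"reversible MLE stopped at residual {delta:.3e} after {max_iter} sweeps",
                stacklevel=2,
            )
        else:
            raise RuntimeError(
                f"reversible MLE did not converge: residual {delta:.3e} after {max_iter} sweeps"
            )
    xrow = x.sum(axis=1)
    p = x / xrow[:, None]
    pi = xrow / xrow.sum()
    return p, pi


@dataclass
class TransitionModel:
    """Fitted MSM results: transition matrix, populations, spectrum.

    ``state_map[j]`` is the original cluster index of retained state ``j``.
    """

    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    eigenvalues: np.ndarray
    lag_ns: float
    state_map: np.ndarray
    mode: str
    count_matrix: CountMatrix | None = None

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def validate(self, atol_row: float = 1e-12, atol_stat: float = 1e-10) -> None:
        p, pi = self.transition_matrix, self.stationary_distribution
        if not np.allclose(p.sum(axis=1), 1.0, atol=atol_row):
            raise AssertionError("rows of P do not sum to 1")
        if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-12:
            raise AssertionError("stationary distribution not a positive probability vector")
        if not np.allclose(pi @ p, pi, atol=atol_stat):
            raise AssertionError("pi is not stationary under P")
        if self.mode == "reversible-mle":
            flux = pi[:, None] * p
            if not np.allclose(flux, flux.T, atol=atol_stat):
                raise AssertionError("detailed balance violated")
        if abs(np.abs(self.eigenvalues[0]) - 1.0) > 1e-10:
            raise AssertionError("leading eigenvalue is not 1")

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales −τ/ln μ_i for the top non-unit eigenvalues;
        NaN where the eigenvalue is complex or outside (0, 1)."""
        mus = self.eigenvalues[1:]
        if n is not None:
            mus = mus[:n]
        out = np.full(len(mus), np.nan)
        for i, mu in enumerate(mus):
            if abs(np.imag(mu)) < 1e-12 and 0 < np.real(mu) < 1:
                out[i] = -self.lag_ns / np.log(np.real(mu))
        return out

    def summary(self) -> str:
        lines = [
            "Markov state model",
            "==================",
            f"states (retained)    : {self.n_states}",
            f"lag time             : {self.lag_ns:g} ns",
            f"estimator            : {self.mode}",
            f"top populations      : "
            + ", ".join(
                f"state {self.state_map[j]}: {self.stationary_distribution[j]:.4f}"
                for j in np.argsort(-self.stationary_distribution)[:5]
            ),
        ]
        ts = self.timescales(5)
        lines.append(
            "implied timescales   : "
            + ", ".join("undef" if np.isnan(t) else f"{t:.3g} ns" for t in ts)
        )
        return "\n".join(lines)


def estimate_transition_matrix(count_matrix: CountMatrix, mode: str = "reversible-mle") -> TransitionModel:
    """Estimate P and π from (ergodically trimmed) counts."""
    c = count_matrix.counts.astype(float)
    rows = c.sum(axis=1)
    if (rows == 0).any():
        raise ValueError("zero row in count matrix; run ergodic_trim first")
    if mode == "naive":
        p = c / rows[:, None]
        pi = _stationary_from_eig(p)
        vals = np.linalg.eigvals(p)
        # modulus-descending, real part breaking ties so the stationary
        # eigenvalue +1 leads a periodic spectrum containing -1
        order = sorted(range(len(vals)), key=lambda i: (-abs(vals[i]), -vals[i].real))
        eigs = vals[order]
        if np.abs(np.imag(eigs)).max() < 1e-12:
            eigs = np.real(eigs)
    elif mode == "reversible-mle":
        p, pi = _reversible_mle(c)
        # similarity-transformed symmetric matrix -> real spectrum
        sqrt_pi = np.sqrt(pi)
        sym = (sqrt_pi[:, None] * p) / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)
        eigs = np.sort(scipy.linalg.eigvalsh(sym))[::-1]
    else:
        raise ValueError(f"unknown estimator mode {mode!r} (use 'naive' or 'reversible-mle')")
    model = TransitionModel(
        transition_matrix=p,
        stationary_distribution=pi,
        eigenvalues=eigs,
        lag_ns=count_matrix.lag_ns,
        state_map=np.arange(count_matrix.n_states),
        mode=mode,
        count_matrix=count_matrix,
    )
    return model


class MarkovStateModel:
    """MSM estimator bound to discrete trajectories and a lag time.

    Parameters
    ----------
    dtrajs : sequence of integer arrays
        Per-trajectory state sequences at uniform spacing ``spacing_ns``.
    lag_ns : float
        Lag time of the model, an integer multiple of ``spacing_ns``.
    mode : {"reversible-mle", "naive"}
    sliding : bool
        Sliding-window transition counting (default) vs independent pairs.
    """

    def __init__(
        self,
        dtrajs: Sequence[np.ndarray],
        lag_ns: float,
        spacing_ns: float,
        mode: str = "reversible-mle",
        sliding: bool = True,
        n_states: int | None = None,
    ):
        self.dtrajs = [np.asarray(d, dtype=int) for d in dtrajs]
        self.lag_ns = lag_ns
        self.spacing_ns = spacing_ns
        self.mode = mode
        self.sliding = sliding
        self.n_states = n_states

    @classmethod
    def from_assignments(cls, assignments, lag_ns: float, **kwargs) -> "MarkovStateModel":
        return cls(assignments.dtrajs(), lag_ns, assignments.spacing_ns, **kwargs)

    def fit(self) -> TransitionModel:
        counts = count_transitions(self.dtrajs, self.lag_ns, self.spacing_ns, self.n_states, self.sliding)
        trimmed, index_map = ergodic_trim(counts)
        result = estimate_transition_matrix(trimmed, self.mode)
        result.state_map = index_map
        result.validate()
        return result


@dataclass
class ImpliedTimescaleSpectrum:
    """Implied timescales t_i(τ) over a scan of lag times.

    ``timescales_ns[l, i]`` is NaN where the i-th eigenvalue at lag l is
    complex or outside (0, 1); the reason is recorded in ``flags[l][i]``.
    """

    lags_ns: np.ndarray
    timescales_ns: np.ndarray
    flags: list[list[str]]
    errors: dict[float, str] = field(default_factory=dict)

    @property
    def rates_per_ns(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.timescales_ns

    def to_csv(self, path: str | Path) -> None:
        lines = ["lag_ns,index,timescale_ns,flag"]
        for l, lag in enumerate(self.lags_ns):
            for i in range(self.timescales_ns.shape[1]):
                t = self.timescales_ns[l, i]
                lines.append(f"{lag:.6g},{i},{'' if np.isnan(t) else format(t, '.8g')},{self.flags[l][i]}")
        Path(path).write_text("\n".join(lines) + "\n")


def implied_timescales(
    dtrajs: Sequence[np.ndarray],
    lags_ns: Sequence[float],
    spacing_ns: float,
    mode: str = "reversible-mle",
    n_timescales: int | None = None,
    sliding: bool = True,
) -> ImpliedTimescaleSpectrum:
    """t_i(τ) = −τ/ln μ_i(τ) for the top non-unit eigenvalues at each lag.

    Lag-independence of the timescales is the Markovianity diagnostic used
    to pick the model lag time.  Estimation failures at individual lags are
    recorded in ``errors`` without aborting the remaining lags.
    """
    rows, flag_rows, errors = [], [], {}
    m_global = None
    for lag in lags_ns:
        try:
            model = MarkovStateModel(dtrajs, lag, spacing_ns, mode=mode, sliding=sliding).fit()
        except Exception as exc:  # noqa: BLE001 - per-lag failures must not abort the scan
            errors[lag] = str(exc)
            rows.append(None)
            flag_rows.append(None)
            continue
        m = model.n_states - 1 if n_timescales is None else min(n_timescales, model.n_states - 1)
        m = min(m, 10) if n_timescales is None else m
        m_global = max(m_global or 0, m)
        mus = model.eigenvalues[1 : 1 + m]
        ts = np.full(m, np.nan)
        fl = [""] * m
        for i, mu in enumerate(mus):
            if abs(np.imag(mu)) > 1e-12:
                fl[i] = "complex"
                ts[i] = -lag / np.log(np.abs(mu)) if 0 < np.abs(mu) < 1 else np.nan
            elif np.real(mu) <= 0:
                fl[i] = "nonpositive"
            elif np.real(mu) >= 1:
                fl[i] = "unit"
            else:
                ts[i] = -lag / np.log(np.real(mu))
        rows.append(ts)
        flag_rows.append(fl)
    m_global = m_global or 0
    out = np.full((len(lags_ns), m_global), np.nan)
    flags: list[list[str]] = []
    for l, (ts, fl) in enumerate(zip(rows, flag_rows)):
        if ts is None:
            flags.append(["error"] * m_global)
            continue
        out[l, : len(ts)] = ts
        flags.append(list(fl) + ["" for _ in range(m_global - len(fl))])
    return ImpliedTimescaleSpectrum(np.asarray(lags_ns, dtype=float), out, flags, errors)


def rank_states(model: TransitionModel, representatives: dict[int, object] | None = None) -> list[tuple[int, float, object]]:
    """States sorted by equilibrium population, descending; ties by index.

    Returns ``(original state index, population, representative pose)``
    triples; the top entry is the predicted binding pose.
    """
    order = sorted(range(model.n_states), key=lambda j: (-model.stationary_distribution[j], model.state_map[j]))
    out = []
    for j in order:
        orig = int(model.state_map[j])
        pose = representatives.get(orig) if representatives else None
        out.append((orig, float(model.stationary_distribution[j]), pose))
    return out
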