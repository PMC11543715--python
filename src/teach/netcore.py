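"""Rate-coded network engine with pooled k-winners-take-all inhibition.

Layers hold unit activations in [0, 1], organised into pools; within
each pool only the k most excited units are allowed above zero
(k-winners-take-all), mimicking fast pooled inhibition.  Projections
carry weight matrices in [0, 1]; net input is fan-in normalised and
scaled by a relative ``wt_scale`` so pathways can be gated per trial
phase.  A trial runs as a sequence of "quarters": settling periods that
may differ in which pathways are gated up or down and which layers are
clamped, producing an expectation (minus) snapshot and an outcome
(plus) snapshot for contrastive learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .plasticity import LearnParams, apply_learning

__all__ = [
    "LayerSpec",
    "ProjectionSpec",
    "QuarterSpec",
    "Layer",
    "Projection",
    "Network",
    "NumericalError",
    "apply_kwta",
    "init_network",
]


class NumericalError(RuntimeError):
    """Raised when settling produces non-finite activations."""


@dataclass(frozen=True)
class LayerSpec:
    """Geometry and inhibition parameters for one layer.

    ``kwta_pct`` is the target fraction of active units per pool.
    ``act_floor`` is an absolute net-input floor: units whose net input
    falls below it stay silent even if they are among the k winners,
    which keeps undriven pools quiet.  ``soft_margin`` loosens the
    inhibition into a graded tail: units whose net input falls within
    the margin below the k-winners threshold keep a small activation
    instead of being cut to zero, approximating the soft pooled
    inhibition of biological circuits and letting a strongly cued
    competitor remain partially co-active.
    """

    name: str
    pool_shape: tuple[int, int]
    n_pools: int = 1
    kwta_pct: float = 0.2
    clampable: bool = True
    gain: float = 6.0
    act_floor: float = 0.15
    soft_margin: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.kwta_pct <= 1.0:
            raise ValueError(f"{self.name}: kwta_pct must be in (0, 1]")
        if min(self.pool_shape) <= 0 or self.n_pools <= 0:
            raise ValueError(f"{self.name}: sizes must be positive")

    @property
    def pool_size(self) -> int:
        return self.pool_shape[0] * self.pool_shape[1]

    @property
    def n_units(self) -> int:
        return self.n_pools * self.pool_size

    @property
    def k(self) -> int:
        return max(1, int(np.floor(self.kwta_pct * self.pool_size + 0.5)))


@dataclass(frozen=True)
class ProjectionSpec:
    """Connectivity and plasticity of one directed projection.

    ``connectivity`` is one of ``"full"``, ``"one_to_one"`` (unit-wise
    identity, requires equal sizes), ``"pool_aligned"`` (full within
    corresponding pools, requires equal pool counts) or
    ``("random_sparse", p)``.  ``src_pools``/``dst_pools`` restrict the
    projection to a subset of pools on either side.  ``learn=None``
    marks a fixed (non-learning) projection.
    """

    src: str
    dst: str
    connectivity: Union[str, tuple] = "full"
    wt_scale: float = 1.0
    learn: Optional[LearnParams] = None
    src_pools: Optional[tuple[int, ...]] = None
    dst_pools: Optional[tuple[int, ...]] = None
    init_weight: Optional[float] = None  # fixed init value; None -> uniform
    init_range: tuple[float, float] = (0.25, 0.75)  # uniform init bounds

    def __post_init__(self) -> None:
        if self.wt_scale < 0:
            raise ValueError("wt_scale must be non-negative")

    @property
    def name(self) -> str:
        return f"{self.src}->{self.dst}"


def apply_kwta(
    net_input: np.ndarray, k: int, gain: float = 6.0
) -> np.ndarray:
    """k-winners-take-all with logistic activation of (net - threshold).

    Exactly ``k`` units are nonzero (ties broken toward the lowest
    index).  The inhibitory threshold is the midpoint between the k-th
    and (k+1)-th largest net inputs, so winners sit on the rising part
    of the logistic.
    """
    net = np.asarray(net_input, dtype=float)
    n = net.size
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    if k == 0:
        return np.zeros(n)
    order = np.argsort(-net, kind="stable")
    winners = order[:k]
    if k < n:
        thr = 0.5 * (net[order[k - 1]] + net[order[k]])
        if net[order[k - 1]] == net[order[k]]:
            # Exact tie at the boundary: drop the threshold slightly so
            # the chosen winners are genuinely above it.
            thr = net[order[k - 1]] - 0.25 / gain
    else:
        thr = net[order[-1]] - 0.25 / gain
    act = np.zeros(n)
    act[winners] = 1.0 / (1.0 + np.exp(-gain * (net[winners] - thr)))
    return act


def _pool_kwta(
    net: np.ndarray, spec: LayerSpec
) -> np.ndarray:
    """Vectorised per-pool kWTA for a whole layer, with net-input floor."""
    P, S, k, gain = spec.n_pools, spec.pool_size, spec.k, spec.gain
    m = net.reshape(P, S)
    rows = np.arange(P)[:, None]
    if k < S:
        part = np.argpartition(-m, (k - 1, k), axis=1)
        win = part[:, :k]
        kth = m[rows[:, 0], part[:, k - 1]]
        nxt = m[rows[:, 0], part[:, k]]
        thr = 0.5 * (kth + nxt)
        tie = kth == nxt
        thr[tie] = kth[tie] - 0.25 / gain
    else:
        win = np.broadcast_to(np.arange(S), (P, S))
        thr = m.min(axis=1) - 0.25 / gain
    act = np.zeros_like(m)
    vals = m[rows, win]
    act[rows, win] = 1.0 / (1.0 + np.exp(-gain * (vals - thr[:, None])))
    if spec.soft_margin > 0.0:
        thr_b = np.broadcast_to(thr[:, None], (P, S))
        tail = (m > thr_b - spec.soft_margin) & (act == 0.0)
        if tail.any():
            act[tail] = 1.0 / (
                1.0 + np.exp(-gain * (m[tail] - thr_b[tail]))
            )
    act[m < spec.act_floor] = 0.0
    return act.reshape(-1)


def _update_projection(
    proj: "Projection",
    x_minus: np.ndarray,
    y_minus: np.ndarray,
    x_plus: np.ndarray,
    y_plus: np.ndarray,
    params: LearnParams,
) -> None:
    """Column-restricted equivalent of :func:`plasticity.apply_learning`.

    Both learning-rule terms vanish on synapses whose receiver was
    silent in both phases, so the update touches only the columns of
    active receivers.  Numerically identical to the reference rule.
    """
    cols = np.flatnonzero((y_plus > 0) | (y_minus > 0))
    if cols.size == 0:
        return
    lam, lr = params.hebb_mix, params.lr
    if lam == 0.0:
        # Purely error-driven: the update also vanishes where the
        # sender was silent in both phases, so restrict rows as well.
        rows = np.flatnonzero((x_plus > 0) | (x_minus > 0))
        if rows.size == 0:
            return
        w = proj.w[np.ix_(rows, cols)]
        delta = lr * (
            np.outer(x_plus[rows], y_plus[cols])
            - np.outer(x_minus[rows], y_minus[cols])
        )
        if params.soft_bounded:
            delta = np.where(delta > 0, delta * (1.0 - w), delta * w)
        if proj.mask is not None:
            delta *= proj.mask[np.ix_(rows, cols)]
        w += delta
        np.clip(w, 0.0, 1.0, out=w)
        proj.w[np.ix_(rows, cols)] = w
        return
    w = proj.w[:, cols]
    yp = y_plus[cols]
    delta = np.zeros_like(w)
    if lam > 0.0:
        delta += lam * lr * (np.outer(x_plus, yp) - w * yp[np.newaxis, :])
    if lam < 1.0:
        delta += (1.0 - lam) * lr * (
            np.outer(x_plus, yp) - np.outer(x_minus, y_minus[cols])
        )
    if params.soft_bounded:
        delta = np.where(delta > 0, delta * (1.0 - w), delta * w)
    if proj.mask is not None:
        delta *= proj.mask[:, cols]
    w += delta
    np.clip(w, 0.0, 1.0, out=w)
    proj.w[:, cols] = w


ClampValue = Union[np.ndarray, Callable[["Network"], np.ndarray]]


@dataclass
class QuarterSpec:
    """One settling period within a trial."""

    n_cycles: int
    clamps: dict[str, ClampValue] = field(default_factory=dict)
    scale_mults: dict[str, float] = field(default_factory=dict)
    snapshot: Optional[str] = None  # "minus" | "plus"


class Layer:
    def __init__(self, spec: LayerSpec):
        self.spec = spec
        self.acts = np.zeros(spec.n_units)

    @property
    def name(self) -> str:
        return self.spec.name


class Projection:
    def __init__(
        self,
        spec: ProjectionSpec,
        src: Layer,
        dst: Layer,
        rng: np.random.Generator,
        expected_act: Optional[float] = None,
    ):
        self.spec = spec
        self.src = src
        self.dst = dst
        n_src, n_dst = src.spec.n_units, dst.spec.n_units
        mask = self._build_mask(n_src, n_dst, rng)
        if spec.init_weight is not None:
            w = np.full((n_src, n_dst), float(spec.init_weight))
        else:
            lo, hi = spec.init_range
            w = rng.uniform(lo, hi, size=(n_src, n_dst))
        self.mask = mask
        self.w = w * mask if mask is not None else w
        fan_in = (
            mask.sum(axis=0) if mask is not None else np.full(n_dst, n_src)
        )
        # Normalise by the expected number of ACTIVE inputs, using the
        # sender layer's own activity fraction, so sparse layers (DG,
        # CA3) drive their targets as strongly as dense ones.
        if expected_act is None:
            expected_act = src.spec.kwta_pct
        self.norm = np.maximum(1.0, fan_in * expected_act)

    def _build_mask(
        self, n_src: int, n_dst: int, rng: np.random.Generator
    ) -> Optional[np.ndarray]:
        spec = self.spec
        conn = spec.connectivity
        sspec, dspec = self.src.spec, self.dst.spec

        block = np.ones((n_src, n_dst))
        if spec.src_pools is not None:
            allowed = np.zeros(n_src)
            for p in spec.src_pools:
                allowed[p * sspec.pool_size : (p + 1) * sspec.pool_size] = 1
            block *= allowed[:, None]
        if spec.dst_pools is not None:
            allowed = np.zeros(n_dst)
            for p in spec.dst_pools:
                allowed[p * dspec.pool_size : (p + 1) * dspec.pool_size] = 1
            block *= allowed[None, :]

        if conn == "full":
            mask = block
        elif conn == "one_to_one":
            if n_src != n_dst:
                raise ValueError(
                    f"{spec.name}: one_to_one needs equal layer sizes"
                )
            mask = np.eye(n_src) * block
        elif conn == "pool_aligned":
            if sspec.n_pools != dspec.n_pools:
                raise ValueError(
                    f"{spec.name}: pool_aligned needs equal pool counts"
                )
            mask = np.zeros((n_src, n_dst))
            for p in range(sspec.n_pools):
                mask[
                    p * sspec.pool_size : (p + 1) * sspec.pool_size,
                    p * dspec.pool_size : (p + 1) * dspec.pool_size,
                ] = 1
            mask *= block
        elif isinstance(conn, tuple) and conn[0] == "random_sparse":
            p = float(conn[1])
            if not 0 < p <= 1:
                raise ValueError(f"{spec.name}: sparsity must be in (0, 1]")
            mask = (rng.random((n_src, n_dst)) < p) * block
        else:
            raise ValueError(f"{spec.name}: unknown connectivity {conn!r}")
        if np.all(mask == 1):
            return None
        return mask

    @property
    def name(self) -> str:
        return self.spec.name

    def net_contribution(
        self, mult: float = 1.0, src_nz: Optional[np.ndarray] = None
    ) -> Optional[np.ndarray]:
        """Scaled, fan-in-normalised drive; None if provably zero.

        ``src_nz`` (indices of nonzero sender units) lets the matmul
        run on the active rows only — sender activity is sparse.
        """
        scale = self.spec.wt_scale * mult
        if scale == 0.0:
            return None
        if src_nz is None:
            src_nz = np.flatnonzero(self.src.acts)
        if src_nz.size == 0:
            return None
        if src_nz.size < self.src.spec.n_units // 2:
            raw = self.src.acts[src_nz] @ self.w[src_nz, :]
        else:
            raw = self.src.acts @ self.w
        return scale * raw / self.norm


class Network:
    """Assembled network: layers, projections, settling, trial dynamics."""

    def __init__(
        self,
        layer_specs: Sequence[LayerSpec],
        projection_specs: Sequence[ProjectionSpec],
        rng: np.random.Generator,
        expected_act: Optional[float] = None,
        dt: float = 0.3,
        settle_tol: float = 0.015,
    ):
        self.layers: dict[str, Layer] = {
            s.name: Layer(s) for s in layer_specs
        }
        if len(self.layers) != len(layer_specs):
            raise ValueError("duplicate layer names")
        self.projections: dict[str, Projection] = {}
        for ps in projection_specs:
            if ps.src not in self.layers or ps.dst not in self.layers:
                raise ValueError(
                    f"projection {ps.name} references unknown layer"
                )
            self.projections[ps.name] = Projection(
                ps, self.layers[ps.src], self.layers[ps.dst], rng,
                expected_act=expected_act,
            )
        self._incoming: dict[str, list[Projection]] = {}
        for proj in self.projections.values():
            self._incoming.setdefault(proj.spec.dst, []).append(proj)
        self.dt = dt
        self.settle_tol = settle_tol

    # ------------------------------------------------------------------
    def acts(self, layer: str) -> np.ndarray:
        return self.layers[layer].acts

    def reset_activity(self) -> None:
        for layer in self.layers.values():
            layer.acts[:] = 0.0

    def compute_net_input(
        self,
        layer: str,
        scale_mults: Mapping[str, float] | None = None,
        nz_cache: Optional[dict] = None,
    ) -> np.ndarray:
        """Fan-in-normalised weighted sum over incoming projections."""
        mults = scale_mults or {}
        net = np.zeros(self.layers[layer].spec.n_units)
        for proj in self._incoming.get(layer, ()):
            src_nz = nz_cache.get(proj.spec.src) if nz_cache else None
            contrib = proj.net_contribution(
                mults.get(proj.name, 1.0), src_nz=src_nz
            )
            if contrib is not None:
                net += contrib
        return net

    def settle(
        self,
        clamps: Mapping[str, np.ndarray],
        n_cycles: int,
        scale_mults: Mapping[str, float] | None = None,
        active_layers: Optional[set[str]] = None,
    ) -> None:
        """Iterate net-input -> kWTA -> rate update for ``n_cycles``.

        Clamped layers are forced to their clamp pattern every cycle.
        A clamp value may also be a ``(pattern, unit_mask)`` pair: only
        the masked units are forced and the rest of the layer settles
        freely (used to drive outcome pools without treating undriven
        pools as negative evidence).  ``active_layers`` optionally
        restricts the update to a subset of layers (all others keep
        their current activity), used to run cheap partial dynamics
        such as semantic pretraining.
        """
        full_clamps: dict[str, np.ndarray] = {}
        partial: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, value in clamps.items():
            layer = self.layers[name]
            if not layer.spec.clampable:
                raise ValueError(f"layer {name} is not clampable")
            if isinstance(value, tuple):
                pattern, unit_mask = value
                partial[name] = (pattern, unit_mask)
                layer.acts[unit_mask] = pattern[unit_mask]
            else:
                full_clamps[name] = value
                layer.acts[:] = value
        free = [
            l
            for l in self.layers.values()
            if l.name not in full_clamps
            and (active_layers is None or l.name in active_layers)
        ]
        srcs = {
            p.spec.src
            for l in free
            for p in self._incoming.get(l.name, ())
        }
        for _ in range(n_cycles):
            nz_cache = {
                name: np.flatnonzero(self.layers[name].acts)
                for name in srcs
            }
            targets = []
            for layer in free:
                net = self.compute_net_input(
                    layer.name, scale_mults, nz_cache=nz_cache
                )
                targets.append(_pool_kwta(net, layer.spec))
            shift = 0.0
            for layer, tgt in zip(free, targets):
                delta = tgt - layer.acts
                layer.acts += self.dt * delta
                if layer.name in partial:
                    pattern, unit_mask = partial[layer.name]
                    layer.acts[unit_mask] = pattern[unit_mask]
                shift = max(shift, float(np.abs(delta).max(initial=0.0)))
            # Activity has converged: further cycles are a no-op.
            if shift < self.settle_tol:
                break
        for layer in free:
            if not np.all(np.isfinite(layer.acts)):
                raise NumericalError(
                    f"non-finite activations in layer {layer.name}"
                )

    def run_trial(
        self,
        base_clamps: Mapping[str, np.ndarray],
        quarters: Sequence[QuarterSpec],
        active_layers: Optional[set[str]] = None,
    ) -> dict[str, dict[str, np.ndarray]]:
        """Run a sequence of settling quarters; collect phase snapshots.

        Quarter clamps may be arrays or callables evaluated on the
        current network state at the start of the quarter (used to copy
        the settled ECin state onto ECout as the outcome target).
        """
        self.reset_activity()
        snapshots: dict[str, dict[str, np.ndarray]] = {}
        for q in quarters:
            clamps = dict(base_clamps)
            for name, value in q.clamps.items():
                clamps[name] = value(self) if callable(value) else value
            self.settle(
                clamps, q.n_cycles, q.scale_mults, active_layers=active_layers
            )
            if q.snapshot:
                snapshots[q.snapshot] = {
                    name: layer.acts.copy()
                    for name, layer in self.layers.items()
                }
        return snapshots

    def learn(
        self,
        snapshots: Mapping[str, Mapping[str, np.ndarray]],
        only: Optional[set[str]] = None,
        lr_override: Optional[Mapping[str, float]] = None,
    ) -> None:
        """Apply the per-projection learning mixture from phase snapshots.

        ``only`` restricts learning to the named projections (used by
        semantic pretraining); ``lr_override`` substitutes learning
        rates per projection name.
        """
        minus = snapshots.get("minus")
        plus = snapshots.get("plus")
        if plus is None:
            raise ValueError("plus-phase snapshot required for learning")
        if minus is None:
            minus = plus
        for proj in self.projections.values():
            params = proj.spec.learn
            if params is None:
                continue
            if only is not None and proj.name not in only:
                continue
            if lr_override and proj.name in lr_override:
                params = LearnParams(
                    lr=lr_override[proj.name],
                    hebb_mix=params.hebb_mix,
                    soft_bounded=params.soft_bounded,
                )
            _update_projection(
                proj,
                minus[proj.spec.src],
                minus[proj.spec.dst],
                plus[proj.spec.src],
                plus[proj.spec.dst],
                params,
            )

    def copy(self) -> "Network":
        """Deep copy of weights and activations (specs are shared).

        Used to branch one trained state into several condition cells
        without re-running the shared phases.
        """
        import copy as _copy

        clone = _copy.copy(self)
        clone.layers = {}
        for name, layer in self.layers.items():
            new_layer = Layer(layer.spec)
            new_layer.acts = layer.acts.copy()
            clone.layers[name] = new_layer
        clone.projections = {}
        for name, proj in self.projections.items():
            new_proj = _copy.copy(proj)
            new_proj.w = proj.w.copy()
            new_proj.src = clone.layers[proj.spec.src]
            new_proj.dst = clone.layers[proj.spec.dst]
            clone.projections[name] = new_proj
        clone._incoming = {}
        for proj in clone.projections.values():
            clone._incoming.setdefault(proj.spec.dst, []).append(proj)
        return clone

    def weight_summary(self) -> list[dict]:
        """Per-projection weight statistics (debugging aid)."""
        rows = []
        for proj in self.projections.values():
            w = proj.w if proj.mask is None else proj.w[proj.mask > 0]
            rows.append(
                {
                    "projection": proj.name,
                    "mean": float(np.mean(w)),
                    "sd": float(np.std(w)),
                    "frac_saturated": float(np.mean(w > 0.95)),
                }
            )
        return rows


def init_network(
    layer_specs: Sequence[LayerSpec],
    projection_specs: Sequence[ProjectionSpec],
    rng: np.random.Generator,
    **kwargs,
) -> Network:
    """Build a network with freshly initialised weights (U[0.25, 0.75])."""
    return Network(layer_specs, projection_specs, rng, **kwargs)
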