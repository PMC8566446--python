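"""Multi-stage stochastic reduction of putative synapses.

The keep probability factorizes over independent stages,

    P_keep = P_dist * f1 * P_SM * P_mu * a3,

applied in the order distance-dependent (per synapse) → f1 (per synapse) →
soft-max cap (per synapse, with the pair count as argument) → mu2 sigmoid
(all-or-none per pair) → a3 (all-or-none per pair). The analytic
expectation `expected_kept` propagates the per-pair count distribution
exactly through the cascade and serves as the independent oracle for the
Monte-Carlo path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

UM = 1e-6


def p_mu(n, mu2):
    """All-or-none keep probability for a pair with n synapses (sigmoid)."""
    if mu2 is None or mu2 <= 0:
        raise ValidationError("mu2 must be positive")
    if n < 1:
        raise ValidationError("n must be >= 1")
    return 1.0 / (1.0 + math.exp(-8.0 / mu2 * (n - mu2)))


def p_softmax(n, soft_max):
    """Per-synapse keep probability of the soft cap, clamped to <= 1."""
    if soft_max is None or soft_max <= 0:
        raise ValidationError("softMax must be positive")
    if n < 1:
        raise ValidationError("n must be >= 1")
    return min(1.0, 2.0 * soft_max /
               ((1.0 + math.exp(-(n - soft_max) / 5.0)) * n))


# ---------------------------------------------------------------------------
# parameters

_DIST_NAMES = {
    "exp": np.exp, "sqrt": np.sqrt, "abs": abs, "min": min, "max": max,
    "step": lambda x: 1.0 if x > 0 else 0.0, "pi": math.pi,
}


def compile_distance_rule(expression):
    """Compile a P(d) expression (d in μm) into a callable of d in metres."""
    if expression is None:
        return None
    if callable(expression):
        return expression
    code = compile(expression, "<distPruning>", "eval")
    for name in code.co_names:
        if name not in _DIST_NAMES and name != "d":
            raise ValidationError(
                f"distPruning expression uses unknown name {name!r}")

    def rule(d_metres):
        env = dict(_DIST_NAMES)
        env["d"] = d_metres / UM
        p = float(eval(code, {"__builtins__": {}}, env))
        if not 0.0 <= p <= 1.0:
            raise ValidationError(
                f"distPruning evaluated to {p} outside [0, 1]")
        return p

    return rule


@dataclass
class PruningParameters:
    """One stage set; any parameter may be None (stage skipped)."""

    f1: float = None
    soft_max: float = None
    mu2: float = None
    a3: float = None
    dist_pruning: object = None   # expression string or callable P(d[m])

    def __post_init__(self):
        if self.f1 is not None and not 0 <= self.f1 <= 1:
            raise ValidationError("f1 must be in [0, 1]")
        if self.soft_max is not None and self.soft_max <= 0:
            raise ValidationError("softMax must be positive")
        if self.mu2 is not None and self.mu2 <= 0:
            raise ValidationError("mu2 must be positive")
        if self.a3 is not None and not 0 <= self.a3 <= 1:
            raise ValidationError("a3 must be in [0, 1]")
        self._dist = compile_distance_rule(self.dist_pruning)

    @classmethod
    def from_dict(cls, block):
        """Parse the JSON pruning block (keys f1, softMax, mu2, a3, distPruning)."""
        if block is None:
            return cls()
        return cls(f1=block.get("f1"), soft_max=block.get("softMax"),
                   mu2=block.get("mu2"), a3=block.get("a3"),
                   dist_pruning=block.get("distPruning"))


@dataclass
class ConnectionSpec:
    """Connectivity-block entry for one (pre type, post type) channel."""

    pre_type: str
    post_type: str
    conductance: tuple = (1e-9, 0.0)      # (mean, std) siemens
    channel_parameters: dict = field(default_factory=dict)
    parameter_file: str = None
    mod_file: str = None
    pruning: PruningParameters = field(default_factory=PruningParameters)
    pruning_other: PruningParameters = None
    gap_junction: bool = False

    def __post_init__(self):
        mean, std = self.conductance
        if mean <= 0:
            raise ValidationError("conductance mean must be positive")
        if std < 0:
            raise ValidationError("conductance std must be non-negative")


def select_params(spec, pre_unit, post_unit):
    """Same unit (both nonzero) → pruning; otherwise pruningOther if present."""
    same = pre_unit == post_unit and pre_unit != 0
    if same or spec.pruning_other is None:
        return spec.pruning
    return spec.pruning_other


def assign_conductance(spec, n, rng_seed=0):
    """n conductances ~ Normal(mean, std) truncated at zero (redraw)."""
    mean, std = spec.conductance
    if std < 0:
        raise ValidationError("conductance std must be non-negative")
    if std == 0:
        return np.full(n, mean)
    rng = np.random.default_rng(rng_seed)
    out = rng.normal(mean, std, size=n)
    while np.any(out <= 0):
        bad = out <= 0
        out[bad] = rng.normal(mean, std, size=int(bad.sum()))
    return out


# ---------------------------------------------------------------------------
# pruning proper

def _pair_rng(seed, pre, post):
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(pre),
                                                         int(post))))


def prune(synapses, params, rng_seed=0, ensure_connected=False):
    """Apply the pruning cascade; returns the kept subset of ``synapses``.

    Synapses are grouped into (pre, post) pairs; each pair uses its own
    seeded substream so the result is independent of iteration order.
    ``ensure_connected`` retains one synapse at random when the soft-max
    stage would otherwise disconnect a pair (off by default: the analytic
    worked expectations assume plain binomial thinning).
    """
    pairs = {}
    for syn in synapses:
        pairs.setdefault(syn.pair, []).append(syn)

    kept_all = []
    for (pre, post), group in sorted(pairs.items()):
        rng = _pair_rng(rng_seed, pre, post)
        # canonical order so the outcome is independent of input ordering
        group = sorted(group, key=lambda s: (tuple(s.voxel), s.section_id))

        if params._dist is not None:
            for s in group:
                if s.distance_to_soma is None:
                    raise ValidationError(
                        "distance-dependent pruning requires path distances")
            group = [s for s in group
                     if rng.random() < params._dist(s.distance_to_soma)]

        if params.f1 is not None and params.f1 < 1:
            group = [s for s in group if rng.random() < params.f1]

        if params.soft_max is not None and group:
            n = len(group)
            q = p_softmax(n, params.soft_max)
            mask = rng.random(n) < q
            if ensure_connected and not mask.any():
                mask[rng.integers(n)] = True
            group = [s for s, k in zip(group, mask) if k]

        if params.mu2 is not None and group:
            if rng.random() >= p_mu(len(group), params.mu2):
                group = []

        if params.a3 is not None and group:
            if rng.random() >= params.a3:
                group = []

        kept_all.extend(group)
    return kept_all


# ---------------------------------------------------------------------------
# analytic expectation oracle

def _binom_pmf(n, k, p):
    return math.comb(n, k) * p ** k * (1 - p) ** (n - k)


def expected_kept(pair_histogram, params, ensure_connected=False):
    """Exact expected synapse count through the cascade.

    ``pair_histogram`` maps initial per-pair synapse count n -> number of
    pairs with that count. Distance-dependent pruning is not representable
    in a count histogram; use :func:`expected_distance_kept` for it.
    """
    if params._dist is not None:
        raise ValidationError(
            "expected_kept cannot evaluate distance-dependent pruning; "
            "see expected_distance_kept")
    total = 0.0
    for n0, n_pairs in pair_histogram.items():
        dist = {int(n0): 1.0}

        if params.f1 is not None and params.f1 < 1:
            dist = _binom_propagate(dist, lambda n: params.f1)

        if params.soft_max is not None:
            dist = _binom_propagate(
                dist, lambda n: p_softmax(n, params.soft_max),
                floor_one=ensure_connected)

        if params.mu2 is not None:
            dist = {m: (p * p_mu(m, params.mu2) if m > 0 else p)
                    for m, p in dist.items()}
            # mass removed by mu2 goes to zero synapses; only E matters

        expect = sum(m * p for m, p in dist.items())
        if params.a3 is not None:
            expect *= params.a3
        total += n_pairs * expect
    return total


def _binom_propagate(dist, q_of_n, floor_one=False):
    out = {}
    for n, p in dist.items():
        if n == 0:
            out[0] = out.get(0, 0.0) + p
            continue
        q = q_of_n(n)
        for k in range(n + 1):
            pk = _binom_pmf(n, k, q)
            kk = k
            if floor_one and k == 0:
                kk = 1
            out[kk] = out.get(kk, 0.0) + p * pk
    return out


def expected_distance_kept(distances, params):
    """Expected synapses kept by the distance rule alone: sum of P(d)."""
    rule = params._dist if isinstance(params, PruningParameters) \
        else compile_distance_rule(params)
    if rule is None:
        return float(len(distances))
    return float(sum(rule(d) for d in distances))
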