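"""External synaptic input: Poisson trains, correlated ensembles, placement.

Correlated ensembles are built from a shared mother Poisson process at the
target rate: every child keeps each mother spike with probability
P = sqrt(C) and merges an independent Poisson process of rate (1 - P) * f,
so the marginal rate is rate-preserving and the pairwise spike-count
correlation equals C.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import TouchnetError, ValidationError
from .pruning import compile_distance_rule

UM = 1e-6


@dataclass
class RateProfile:
    """Piecewise-constant firing rate: frequency[i] on [start[i], end[i])."""

    start: np.ndarray
    end: np.ndarray
    frequency: np.ndarray

    def __post_init__(self):
        self.start = np.atleast_1d(np.asarray(self.start, dtype=float))
        self.end = np.atleast_1d(np.asarray(self.end, dtype=float))
        self.frequency = np.atleast_1d(np.asarray(self.frequency, dtype=float))
        if not len(self.start) == len(self.end) == len(self.frequency):
            raise ValidationError("start, end, frequency must have equal length")
        if np.any(self.end <= self.start):
            raise ValidationError("intervals must satisfy start < end")
        if np.any(self.frequency < 0):
            raise ValidationError("frequency must be non-negative")
        order = np.argsort(self.start)
        self.start, self.end, self.frequency = (
            self.start[order], self.end[order], self.frequency[order])
        if np.any(self.end[:-1] > self.start[1:]):
            raise ValidationError("rate intervals must not overlap")

    @classmethod
    def constant(cls, frequency, duration):
        return cls([0.0], [duration], [frequency])

    def scaled(self, factor):
        return RateProfile(self.start, self.end, self.frequency * factor)


def poisson_train(profile, duration, rng=None):
    """Piecewise-homogeneous Poisson spike times on [0, duration], sorted."""
    if duration <= 0:
        raise ValidationError("duration must be positive")
    rng = np.random.default_rng(rng)
    times = []
    for s, e, f in zip(profile.start, profile.end, profile.frequency):
        s, e = max(0.0, s), min(duration, e)
        if e <= s or f <= 0:
            continue
        n = rng.poisson(f * (e - s))
        times.append(rng.uniform(s, e, size=n))
    if not times:
        return np.zeros(0)
    return np.sort(np.concatenate(times))


def correlated_trains(k, profile, correlation, duration, rng=None):
    """k spike trains with pairwise spike-count correlation ``correlation``."""
    if not 0 <= correlation <= 1:
        raise ValidationError("correlation must be in [0, 1]")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(rng)
    p = math.sqrt(correlation)
    mother = poisson_train(profile, duration, rng)
    trains = []
    for _ in range(k):
        if p >= 1.0:
            trains.append(mother.copy())
            continue
        kept = mother[rng.random(len(mother)) < p] if p > 0 else np.zeros(0)
        indep = poisson_train(profile.scaled(1.0 - p), duration, rng)
        trains.append(np.sort(np.concatenate([kept, indep])))
    return trains


def pairwise_count_correlation(trains, duration, bin_width=0.1):
    """Mean pairwise Pearson correlation of binned spike counts."""
    edges = np.arange(0.0, duration + bin_width, bin_width)
    counts = np.array([np.histogram(t, bins=edges)[0] for t in trains],
                      dtype=float)
    c = np.corrcoef(counts)
    iu = np.triu_indices(len(trains), k=1)
    vals = c[iu]
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# configuration blocks

@dataclass
class InputBlockSpec:
    """One input channel (e.g. 'Ctx') within a target block."""

    name: str
    generator: str = "poisson"          # 'poisson' | 'csv'
    profile: RateProfile = None
    population_correlation: float = 0.0
    n_inputs: int = None
    synapse_density: str = None         # expression in d (μm) or None
    type: str = "AMPA_NMDA"
    conductance: tuple = (5e-10, 0.0)
    mod_file: str = None
    parameter_file: str = None
    csv_file: str = None

    def __post_init__(self):
        if self.generator not in ("poisson", "csv"):
            raise ValidationError(f"unknown generator {self.generator!r}")
        if not 0 <= self.population_correlation <= 1:
            raise ValidationError("populationCorrelation must be in [0, 1]")

    @classmethod
    def from_dict(cls, name, block):
        profile = None
        if "frequency" in block:
            start = block.get("start", 0.0)
            end = block.get("end")
            profile = RateProfile(start, end, block["frequency"])
        return cls(
            name=name,
            generator=block.get("generator", "poisson"),
            profile=profile,
            population_correlation=block.get("populationCorrelation", 0.0),
            n_inputs=block.get("nInputs"),
            synapse_density=block.get("synapseDensity"),
            type=block.get("type", "AMPA_NMDA"),
            conductance=tuple(np.atleast_1d(block.get("conductance", 5e-10)))
            if not np.isscalar(block.get("conductance", 5e-10))
            else (block.get("conductance", 5e-10), 0.0),
            mod_file=block.get("modFile"),
            parameter_file=block.get("parameterFile"),
            csv_file=block.get("csvFile"),
        )


def resolve_target_block(config, neuron_id, morphology_key, neuron_type):
    """Pick the most specific matching target block: id > morphology > type.

    ``config`` maps block names (a neuron id string, a morphology key or a
    neuron type) to dicts of input-channel blocks. Returns the channel dict
    of the chosen block, or an empty dict when nothing matches.
    """
    for key in (str(neuron_id), morphology_key, neuron_type):
        if key is not None and key in config:
            return config[key]
    return {}


# ---------------------------------------------------------------------------
# synapse placement on dendrites

@dataclass
class InputLocation:
    section_id: int
    offset: float
    path_distance: float      # metres
    position: np.ndarray


def _dendrite_segments(morph):
    rows = list(morph.segments("dendrite"))
    if not rows:
        raise ValidationError("morphology has no dendrite")
    dist = morph.path_distances()
    pr = np.array([a for a, _ in rows])
    cr = np.array([b for _, b in rows])
    lengths = np.linalg.norm(morph.xyz[cr] - morph.xyz[pr], axis=1)
    return rows, pr, cr, lengths, dist


def place_input_synapses(morph, n_inputs=None, density=None, rng=None):
    """Sample input locations along the dendritic cable.

    Linear density ∝ density(d) (an expression of path distance d in μm,
    density per μm). With ``n_inputs`` the count is exact (density-weighted
    sampling); with density only, the count is Poisson(∫ density dl).
    """
    rng = np.random.default_rng(rng)
    rows, pr, cr, lengths, dist = _dendrite_segments(morph)
    rule = compile_distance_rule_density(density)
    mid = dist[pr] + lengths / 2
    weights = np.array([rule(d) for d in mid]) * lengths / UM
    if np.any(weights < 0):
        raise ValidationError("synapse density evaluated negative")
    total = float(weights.sum())

    if n_inputs is None:
        n_inputs = int(rng.poisson(total))
    n_inputs = int(n_inputs)
    if n_inputs == 0:
        return []
    if total <= 0:
        raise ValidationError("synapse density is zero everywhere on the dendrite")

    idx = rng.choice(len(lengths), size=n_inputs, p=weights / total)
    out = []
    for i in idx:
        t = rng.random()
        prow, crow = pr[i], cr[i]
        pos = morph.xyz[prow] + t * (morph.xyz[crow] - morph.xyz[prow])
        out.append(InputLocation(int(morph.ids[crow]), float(t),
                                 float(dist[prow] + t * lengths[i]), pos))
    return out


def compile_distance_rule_density(density):
    """Density expressions reuse the P(d) expression machinery but are not
    clamped to [0, 1]."""
    if density is None:
        return lambda d: 1.0
    if callable(density):
        return density
    import math as _m

    code = compile(density, "<synapseDensity>", "eval")
    names = {"exp": np.exp, "sqrt": np.sqrt, "abs": abs,
             "step": lambda x: 1.0 if x > 0 else 0.0, "pi": _m.pi}
    for name in code.co_names:
        if name not in names and name != "d":
            raise ValidationError(
                f"synapseDensity expression uses unknown name {name!r}")

    def rule(d_metres):
        env = dict(names)
        env["d"] = d_metres / UM
        return float(eval(code, {"__builtins__": {}}, env))

    return rule


# ---------------------------------------------------------------------------
# spike-train sets

@dataclass
class InputChannel:
    name: str
    spikes: np.ndarray
    location: InputLocation
    metadata: dict = field(default_factory=dict)


@dataclass
class SpikeTrainSet:
    """Per-neuron external input channels."""

    channels: dict = field(default_factory=dict)   # neuron id -> [InputChannel]

    def add(self, neuron_id, channel):
        self.channels.setdefault(neuron_id, []).append(channel)

    def n_channels(self, neuron_id):
        return len(self.channels.get(neuron_id, []))


def scale_inputs(train_set, neuron_id, factor, rng=None):
    """Scale the number of input channels of one neuron by ``factor``."""
    if factor < 0:
        raise ValidationError("factor must be non-negative")
    rng = np.random.default_rng(rng)
    chans = train_set.channels.get(neuron_id, [])
    target = int(round(len(chans) * factor))
    if target == len(chans):
        return train_set
    if target < len(chans):
        keep = rng.choice(len(chans), size=target, replace=False)
        train_set.channels[neuron_id] = [chans[i] for i in sorted(keep)]
    else:
        extra = rng.choice(len(chans), size=target - len(chans), replace=True)
        train_set.channels[neuron_id] = chans + [chans[i] for i in extra]
    return train_set


def read_csv_spikes(path):
    """One spike train per row; values in seconds; rows are sorted."""
    trains = []
    with open(path) as fh:
        for rowno, raw in enumerate(fh):
            line = raw.strip()
            if not line:
                trains.append(np.zeros(0))
                continue
            try:
                vals = np.array([float(v) for v in line.replace(",", " ").split()])
            except ValueError:
                raise TouchnetError(
                    f"non-numeric token in CSV spike file, row {rowno}") from None
            trains.append(np.sort(vals))
    return trains


def virtual_neuron_spikes(placement, prototypes, trains):
    """Attach predefined spike trains to virtual neurons.

    ``trains`` maps neuron id -> spike-time array. Every targeted neuron
    must belong to a prototype flagged virtual.
    """
    activity = {}
    by_id = {n.id: n for n in placement.neurons}
    for nid, spikes in trains.items():
        n = by_id.get(nid)
        if n is None:
            raise ValidationError(f"unknown neuron id {nid}")
        proto = prototypes[n.prototype]
        if not proto.is_virtual:
            raise ValidationError(
                f"neuron {nid} (prototype {n.prototype}) is not virtual")
        activity[nid] = np.sort(np.asarray(spikes, dtype=float))
    return activity


def generate_inputs(placement, morphologies, input_config, duration,
                    rng_seed=0, morphology_keys=None):
    """Build a SpikeTrainSet for a placed network from an input config.

    ``input_config`` maps target-block names to channel dicts (JSON layout).
    Per-neuron, per-channel substreams keep regeneration independent.
    """
    out = SpikeTrainSet()
    for n in placement.neurons:
        mkey = (morphology_keys or {}).get(n.id, n.prototype)
        block = resolve_target_block(input_config, n.id, mkey, n.neuron_type)
        for cname in sorted(block):
            spec = InputBlockSpec.from_dict(cname, block[cname])
            # crc32 gives a run-independent channel key (hash() is salted)
            rng = np.random.default_rng(
                np.random.SeedSequence((int(rng_seed), int(n.id),
                                        zlib.crc32(cname.encode()))))
            morph = morphologies[n.prototype]
            locs = place_input_synapses(
                morph, n_inputs=spec.n_inputs,
                density=spec.synapse_density, rng=rng)
            if spec.generator == "csv":
                csv_trains = read_csv_spikes(spec.csv_file)
                trains = [csv_trains[i % len(csv_trains)]
                          for i in range(len(locs))]
            else:
                profile = spec.profile or RateProfile.constant(1.0, duration)
                trains = correlated_trains(
                    len(locs), profile, spec.population_correlation,
                    duration, rng)
            for loc, spikes in zip(locs, trains):
                out.add(n.id, InputChannel(
                    cname, spikes, loc,
                    metadata={"type": spec.type, "modFile": spec.mod_file,
                              "conductance": spec.conductance}))
    return out
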