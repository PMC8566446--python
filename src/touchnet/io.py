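"""Network configuration parsing, seed management and the HDF5 container.

The JSON configuration is hierarchically organised into blocks
``RandomSeed``, ``Volume``, ``PopulationUnits``, ``Connectivity`` and
``Neurons`` (SI units throughout). Pipeline products are persisted in a
single HDF5 file; synapse coordinates are stored as integer voxel indices
plus the grid origin so they are exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .detection import VOXEL_SIZE, GapJunction, PutativeSynapse
from .errors import DependencyError, TouchnetError, ValidationError
from .placement import (NeuronPlacement, PlacementResult, PopulationUnitSpec,
                        VolumeSpec)
from .pruning import ConnectionSpec, PruningParameters
from .swc import NeuronPrototype

CONTAINER_VERSION = 1
DATA_DIR = Path(__file__).parent / "data"

#: reference neuron density used by init (per m^3); 0.5 mm cube -> 10,062
REFERENCE_DENSITY = 10_062 / (0.5e-3 ** 3)


@dataclass
class NeuronGroupSpec:
    """One Neurons-block entry: a prototype plus its instantiation count."""

    prototype: NeuronPrototype
    num: int
    rotation_mode: str = "random"
    volume_id: str = None
    hoc: str = None


@dataclass
class NetworkConfig:
    random_seed: dict
    volumes: dict                     # name -> VolumeSpec
    population_units: list            # of PopulationUnitSpec
    connectivity: dict                # (pre type, post type) -> ConnectionSpec
    neurons: dict                     # template name -> NeuronGroupSpec

    def seed_for(self, stage):
        if stage in self.random_seed:
            return int(self.random_seed[stage])
        return int(self.random_seed.get("masterseed", 0))


_KNOWN_TOP = {"RandomSeed", "Volume", "PopulationUnits", "Connectivity",
              "Neurons"}
_KNOWN_PRUNING = {"f1", "softMax", "mu2", "a3", "distPruning"}


def _expand_data(value, base_dir):
    if isinstance(value, str) and value.startswith("$DATA"):
        return str(DATA_DIR) + value[len("$DATA"):]
    if isinstance(value, str) and base_dir is not None and \
            not Path(value).is_absolute():
        return str(Path(base_dir) / value)
    return value


def parse_config(path):
    """Parse and validate a network configuration JSON file."""
    path = Path(path)
    raw = json.loads(path.read_text())
    base = path.parent
    for key in raw:
        if key not in _KNOWN_TOP:
            warnings.warn(f"unknown configuration block {key!r} ignored")

    seeds = raw.get("RandomSeed", {})

    volumes = {}
    for name, block in raw.get("Volume", {}).items():
        volumes[name] = VolumeSpec(
            name=name,
            type=block.get("type", "cube"),
            d_min=block.get("dMin", 1.5e-5),
            mesh_file=_expand_data(block.get("meshFile"), base),
            mesh_bin_width=block.get("meshBinWidth", 1e-4),
            side=block.get("side", 5e-4),
            centre=tuple(block.get("centre", (0.0, 0.0, 0.0))),
        )

    units = []
    for block in raw.get("PopulationUnits", []):
        units.append(PopulationUnitSpec(
            unit_id=block["unitID"],
            volume=block.get("volume", next(iter(volumes), None)),
            neuron_types=block.get("neuronTypes", []),
            fraction=block.get("fraction", 0.0),
        ))
    by_type = {}
    for u in units:
        for t in u.neuron_types:
            by_type[t] = by_type.get(t, 0.0) + u.fraction
    for t, tot in by_type.items():
        if tot > 1 + 1e-12:
            raise ValidationError(
                f"PopulationUnits: fractions for type {t!r} sum to {tot} > 1")

    connectivity = {}
    for pair_key, block in raw.get("Connectivity", {}).items():
        pre, post = (s.strip() for s in pair_key.split(","))
        for pk in block.get("pruning", {}) or {}:
            if pk not in _KNOWN_PRUNING:
                warnings.warn(f"unknown pruning key {pk!r} in {pair_key!r}")
        try:
            spec = ConnectionSpec(
                pre_type=pre, post_type=post,
                conductance=tuple(block.get("conductance", (1e-9, 0.0))),
                channel_parameters=block.get("channelParameters", {}),
                parameter_file=_expand_data(block.get("parameterFile"), base),
                mod_file=block.get("modFile"),
                pruning=PruningParameters.from_dict(block.get("pruning")),
                pruning_other=(PruningParameters.from_dict(block["pruningOther"])
                               if block.get("pruningOther") is not None else None),
                gap_junction=block.get("gapJunction", False),
            )
        except ValidationError as e:
            raise ValidationError(f"Connectivity[{pair_key!r}]: {e}") from None
        connectivity[(pre, post)] = spec

    neurons = {}
    for name, block in raw.get("Neurons", {}).items():
        ntype = block.get("type", name.split("_")[0])
        proto = NeuronPrototype(
            name=name, neuron_type=ntype,
            morphology_path=_expand_data(block.get("morphology"), base),
            parameter_set=block.get("parameters"),
            mechanism_set=block.get("mechanisms"),
            modulation_set=block.get("modulation"),
            is_virtual=block.get("neuronType", "neuron") == "virtualNeuron",
        )
        vol = block.get("volumeID")
        if vol is not None and vol not in volumes:
            raise ValidationError(f"Neurons[{name!r}]: unknown volumeID {vol!r}")
        neurons[name] = NeuronGroupSpec(
            prototype=proto, num=int(block.get("num", 1)),
            rotation_mode=block.get("rotationMode", "random"),
            volume_id=vol, hoc=block.get("hoc"))

    declared_types = {g.prototype.neuron_type for g in neurons.values()}
    for pre, post in connectivity:
        for t in (pre, post):
            if t not in declared_types:
                raise ValidationError(
                    f"Connectivity references undeclared neuron type {t!r}")

    return NetworkConfig(seeds, volumes, units, connectivity, neurons)


def config_hash(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# init

_BALL_AND_STICK_A = """# id type x y z radius parent
1 1 0 0 0 6 -1
2 3 10 0 0 1 1
3 3 120 0 0 0.6 2
4 2 -8 0 0 0.5 1
5 2 -8 0 150 0.4 4
6 2 100 0 150 0.4 5
7 2 100 0 -20 0.4 6
"""

_BALL_AND_STICK_B = """# id type x y z radius parent
1 1 0 0 0 6 -1
2 3 0 10 0 1 1
3 3 0 130 0 0.6 2
4 2 0 -8 0 0.5 1
5 2 0 -8 140 0.4 4
6 2 0 90 140 0.4 5
7 2 0 90 -20 0.4 6
"""


def init_config(out_dir, size, rng_seed=0, overwrite=False):
    """Generate a self-contained configuration for a cube-bounded network.

    The cube is sized so that ``size`` neurons sit at the reference striatal
    density; two ball-and-stick prototypes are written next to the config.
    """
    if size <= 0:
        raise ValidationError("size must be positive")
    out_dir = Path(out_dir)
    cfg_path = out_dir / "network-config.json"
    if cfg_path.exists() and not overwrite:
        raise TouchnetError(f"{cfg_path} exists; pass overwrite to replace it")
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "morphologies").mkdir(exist_ok=True)
    (out_dir / "morphologies" / "typeA.swc").write_text(_BALL_AND_STICK_A)
    (out_dir / "morphologies" / "typeB.swc").write_text(_BALL_AND_STICK_B)

    side = (size / REFERENCE_DENSITY) ** (1 / 3)
    ss = np.random.SeedSequence(rng_seed)
    place_s, detect_s, prune_s, input_s = (
        int(s) for s in ss.generate_state(4))
    n_a = size // 2
    n_b = size - n_a
    config = {
        "RandomSeed": {"masterseed": int(rng_seed), "place": place_s,
                       "detect": detect_s, "prune": prune_s,
                       "input": input_s},
        "Volume": {"Cube": {"type": "cube", "side": side,
                            "centre": [0.0, 0.0, 0.0], "dMin": 1.0e-5}},
        "PopulationUnits": [],
        "Connectivity": {
            "typeA,typeB": {
                "conductance": [5e-10, 1e-10],
                "channelParameters": {"tau1": 1.3e-3, "tau2": 12e-3,
                                      "failRate": 0.7},
                "modFile": "tmGabaA",
                "pruning": {"f1": 0.5, "mu2": 3, "a3": 0.7},
            },
            "typeB,typeA": {
                "conductance": [5e-10, 1e-10],
                "modFile": "tmGabaA",
                "pruning": {"f1": 0.5, "softMax": 8, "mu2": 3, "a3": 0.7},
            },
            "typeA,typeA": {
                "conductance": [5e-10, 1e-10],
                "modFile": "tmGabaA",
                "pruning": {"f1": 0.7, "a3": 0.9},
            },
            "typeB,typeB": {
                "conductance": [5e-10, 1e-10],
                "modFile": "tmGabaA",
                "pruning": {"f1": 0.7, "a3": 0.9},
            },
        },
        "Neurons": {
            "typeA_0": {"type": "typeA",
                        "morphology": "morphologies/typeA.swc",
                        "num": int(n_a), "rotationMode": "random",
                        "volumeID": "Cube"},
            "typeB_0": {"type": "typeB",
                        "morphology": "morphologies/typeB.swc",
                        "num": int(n_b), "rotationMode": "random",
                        "volumeID": "Cube"},
        },
    }
    cfg_path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    return cfg_path


# ---------------------------------------------------------------------------
# container

@dataclass
class NetworkContainer:
    placement: PlacementResult = None
    putative_synapses: list = field(default_factory=list)
    synapses: list = field(default_factory=list)
    gap_junctions: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)   # nid -> list of dicts
    meta: dict = field(default_factory=dict)
    grid_origin: np.ndarray = None
    voxel_size: float = VOXEL_SIZE
    pruned: bool = False

    def check_consistency(self):
        if self.placement is None:
            return
        n = len(self.placement)
        for s in list(self.putative_synapses) + list(self.synapses):
            if not (0 <= s.pre_id < n and 0 <= s.post_id < n):
                raise TouchnetError("synapse references unknown neuron id")


_STR = h5py.string_dtype()


def write_network(container, path):
    container.check_consistency()
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["version"] = CONTAINER_VERSION
        meta.attrs["pruned"] = container.pruned
        meta.attrs["meta_json"] = json.dumps(container.meta)
        meta.attrs["voxel_size"] = container.voxel_size
        if container.grid_origin is not None:
            meta.attrs["grid_origin"] = np.asarray(container.grid_origin)

        if container.placement is not None:
            g = f.create_group("placement")
            p = container.placement
            g.create_dataset("positions", data=p.positions)
            g.create_dataset("rotations",
                             data=np.array([n.rotation for n in p.neurons])
                             .reshape(-1, 3, 3))
            g.create_dataset("prototype",
                             data=[n.prototype for n in p.neurons], dtype=_STR)
            g.create_dataset("neuron_type",
                             data=[n.neuron_type for n in p.neurons], dtype=_STR)
            g.create_dataset("volume_id",
                             data=[str(n.volume_id) for n in p.neurons],
                             dtype=_STR)
            g.create_dataset("population_unit",
                             data=[n.population_unit for n in p.neurons],
                             dtype=np.int64)
            g.create_dataset("padding_positions", data=p.padding_positions)

        _write_synapses(f, "putative_synapses", container.putative_synapses)
        _write_synapses(f, "synapses", container.synapses)
        _write_gap_junctions(f, "gap_junctions", container.gap_junctions)

        if container.inputs:
            g = f.create_group("inputs")
            for nid, channels in container.inputs.items():
                ng = g.create_group(str(nid))
                for k, ch in enumerate(channels):
                    cg = ng.create_group(str(k))
                    cg.create_dataset("spikes", data=np.asarray(ch["spikes"]))
                    cg.attrs["name"] = ch.get("name", "")
                    cg.attrs["section_id"] = ch.get("section_id", -1)
                    cg.attrs["offset"] = ch.get("offset", 0.0)
                    cg.attrs["distance"] = ch.get("distance", 0.0)


def _write_synapses(f, name, synapses):
    g = f.create_group(name)
    ints = np.array([[s.pre_id, s.post_id, *s.voxel, s.section_id]
                     for s in synapses], dtype=np.int64).reshape(-1, 6)
    floats = np.array([[*s.position, s.section_offset, s.distance_to_soma]
                       for s in synapses], dtype=np.float64).reshape(-1, 5)
    g.create_dataset("int_data", data=ints)
    g.create_dataset("float_data", data=floats)


def _write_gap_junctions(f, name, gjs):
    g = f.create_group(name)
    ints = np.array([[j.neuron_a, j.neuron_b, *j.voxel, j.section_a,
                      j.section_b] for j in gjs],
                    dtype=np.int64).reshape(-1, 7)
    floats = np.array([[*j.position, j.offset_a, j.offset_b] for j in gjs],
                      dtype=np.float64).reshape(-1, 5)
    g.create_dataset("int_data", data=ints)
    g.create_dataset("float_data", data=floats)


def read_network(path):
    path = Path(path)
    if not path.exists():
        raise DependencyError(f"network container {path} does not exist")
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise TouchnetError(f"{path} is not a network container")
        version = int(f["meta"].attrs["version"])
        if version != CONTAINER_VERSION:
            raise TouchnetError(
                f"container version {version} needs migration to "
                f"{CONTAINER_VERSION}")
        c = NetworkContainer()
        c.meta = json.loads(f["meta"].attrs["meta_json"])
        c.pruned = bool(f["meta"].attrs["pruned"])
        c.voxel_size = float(f["meta"].attrs["voxel_size"])
        if "grid_origin" in f["meta"].attrs:
            c.grid_origin = np.array(f["meta"].attrs["grid_origin"])

        if "placement" in f:
            g = f["placement"]
            neurons = []
            pos = g["positions"][()]
            rot = g["rotations"][()]
            proto = [s.decode() for s in g["prototype"][()]]
            ntype = [s.decode() for s in g["neuron_type"][()]]
            vol = [s.decode() for s in g["volume_id"][()]]
            unit = g["population_unit"][()]
            for i in range(len(pos)):
                neurons.append(NeuronPlacement(
                    id=i, prototype=proto[i], neuron_type=ntype[i],
                    position=pos[i], rotation=rot[i], volume_id=vol[i],
                    population_unit=int(unit[i])))
            c.placement = PlacementResult(neurons,
                                          g["padding_positions"][()])
        for gname, target in (("putative_synapses", c.putative_synapses),
                              ("synapses", c.synapses)):
            if gname not in f:
                continue
            ints = f[gname]["int_data"][()]
            floats = f[gname]["float_data"][()]
            for r in range(len(ints)):
                target.append(PutativeSynapse(
                    int(ints[r, 0]), int(ints[r, 1]),
                    tuple(int(v) for v in ints[r, 2:5]),
                    floats[r, 0:3].copy(), int(ints[r, 5]),
                    float(floats[r, 3]), float(floats[r, 4])))
        if "gap_junctions" in f:
            ints = f["gap_junctions"]["int_data"][()]
            floats = f["gap_junctions"]["float_data"][()]
            for r in range(len(ints)):
                c.gap_junctions.append(GapJunction(
                    int(ints[r, 0]), int(ints[r, 1]),
                    tuple(int(v) for v in ints[r, 2:5]),
                    floats[r, 0:3].copy(), int(ints[r, 5]),
                    float(floats[r, 3]), int(ints[r, 6]),
                    float(floats[r, 4])))
        if "inputs" in f:
            for nid in f["inputs"]:
                chans = []
                ng = f["inputs"][nid]
                for k in sorted(ng, key=int):
                    cg = ng[k]
                    chans.append({
                        "spikes": cg["spikes"][()],
                        "name": cg.attrs.get("name", ""),
                        "section_id": int(cg.attrs.get("section_id", -1)),
                        "offset": float(cg.attrs.get("offset", 0.0)),
                        "distance": float(cg.attrs.get("distance", 0.0)),
                    })
                c.inputs[int(nid)] = chans
    c.check_consistency()
    return c
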