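"""Stage runners tying configuration, placement, detection, pruning and
input generation together over a network directory."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import detection, inputs, placement, pruning
from .errors import DependencyError, TouchnetError
from .io import (NetworkContainer, config_hash, parse_config, read_network,
                 write_network)
from .swc import read_swc

CONTAINER_NAME = "network.hdf5"
CONFIG_NAME = "network-config.json"


def _paths(network_dir):
    network_dir = Path(network_dir)
    cfg = network_dir / CONFIG_NAME
    if not cfg.exists():
        raise DependencyError(f"{cfg} not found; run init first")
    return cfg, network_dir / CONTAINER_NAME


def _load(network_dir, require=None):
    cfg_path, con_path = _paths(network_dir)
    config = parse_config(cfg_path)
    if not con_path.exists():
        if require:
            raise DependencyError(
                f"network container missing; run {require} first")
        container = NetworkContainer()
        container.meta = {"config_hash": config_hash(cfg_path),
                          "seeds": config.random_seed}
        return config, container, con_path
    return config, read_network(con_path), con_path


def run_place(network_dir, seed=None):
    config, container, con_path = _load(network_dir)
    if len(config.volumes) != 1:
        raise TouchnetError("exactly one volume is supported per placement run")
    volume = next(iter(config.volumes.values()))
    counts = {name: g.num for name, g in config.neurons.items()}
    rotation_modes = {name: g.rotation_mode for name, g in config.neurons.items()}
    neuron_types = {name: g.prototype.neuron_type
                    for name, g in config.neurons.items()}
    result = placement.place_neurons(
        volume, counts,
        rng_seed=seed if seed is not None else config.seed_for("place"),
        rotation_modes=rotation_modes, neuron_types=neuron_types)
    placement.assign_population_units(
        result, config.population_units,
        rng_seed=config.seed_for("place") + 1)
    container.placement = result
    container.putative_synapses = []
    container.synapses = []
    container.gap_junctions = []
    container.pruned = False
    write_network(container, con_path)
    return result


def _load_morphologies(config):
    return {name: read_swc(g.prototype.morphology_path)
            for name, g in config.neurons.items()}


def run_detect(network_dir, seed=None, use_hypervoxels=False):
    config, container, con_path = _load(network_dir, require="place")
    if container.placement is None:
        raise DependencyError("no placement in container; run place first")
    morphologies = _load_morphologies(config)
    allowed = [k for k, spec in config.connectivity.items()
               if not spec.gap_junction]
    gj_pairs = [k for k, spec in config.connectivity.items()
                if spec.gap_junction]
    synapses, gjs = detection.detect_network(
        container.placement, morphologies, allowed, gj_pairs,
        use_hypervoxels=use_hypervoxels)
    container.putative_synapses = synapses
    container.synapses = []
    container.gap_junctions = gjs
    container.pruned = False
    write_network(container, con_path)
    return synapses, gjs


def run_prune(network_dir, seed=None):
    config, container, con_path = _load(network_dir, require="detect")
    if container.placement is None or (not container.putative_synapses
                                       and not container.gap_junctions):
        raise DependencyError("no putative synapses in container; "
                              "run detect first")
    prune_seed = seed if seed is not None else config.seed_for("prune")
    units = {n.id: n.population_unit for n in container.placement.neurons}
    types = {n.id: n.neuron_type for n in container.placement.neurons}

    by_type = {}
    for s in container.putative_synapses:
        by_type.setdefault((types[s.pre_id], types[s.post_id]), []).append(s)
    kept = []
    for pair_type, group in sorted(by_type.items()):
        spec = config.connectivity.get(pair_type)
        if spec is None:
            continue
        # split by unit relationship so each side uses its parameter set
        same, other = [], []
        for s in group:
            u1, u2 = units[s.pre_id], units[s.post_id]
            (same if (u1 == u2 and u1 != 0) else other).append(s)
        kept.extend(pruning.prune(same, spec.pruning, rng_seed=prune_seed))
        kept.extend(pruning.prune(
            other, pruning.select_params(spec, 1, 2), rng_seed=prune_seed))
    container.synapses = kept
    container.pruned = True
    write_network(container, con_path)
    return kept


def run_input(network_dir, duration, input_config_path, seed=None):
    config, container, con_path = _load(network_dir, require="place")
    if container.placement is None:
        raise DependencyError("no placement in container; run place first")
    input_config = json.loads(Path(input_config_path).read_text())
    morphologies = _load_morphologies(config)
    trains = inputs.generate_inputs(
        container.placement, morphologies, input_config, duration,
        rng_seed=seed if seed is not None else config.seed_for("input"))
    container.inputs = {
        nid: [{"spikes": ch.spikes, "name": ch.name,
               "section_id": ch.location.section_id,
               "offset": ch.location.offset,
               "distance": ch.location.path_distance}
              for ch in channels]
        for nid, channels in trains.channels.items()}
    write_network(container, con_path)
    return trains
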