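# touchnet

Microcircuit connectivity prediction for large-scale neuron-network
simulation setup. The pipeline places neuron somas inside a mesh- or
cube-bounded volume under a minimum-separation constraint, rasterizes SWC
morphologies into 3 μm voxels (grouped into 100³-voxel hypervoxels for
parallel decomposition), detects putative synapses where axons and
dendrites co-occupy a voxel, reduces them with a multi-stage stochastic
pruning rule

    P_keep = P_dist · f1 · P_SM · P_mu · a3

and generates external synaptic input as correlated Poisson spike trains
(shared mother process thinned with probability √C). A companion toolbox
repairs and augments SWC reconstructions: z-jump correction
(align/split/tilt/join), grafting of cut neurites, shrinkage correction,
unravelling and length-preserving random variability
(jitter/twist/rotate/scale3d).

## Layout

| module                 | contents                                                |
|------------------------|---------------------------------------------------------|
| `touchnet.swc`         | SWC read/write, validation, path distances, transforms  |
| `touchnet.curation`    | morphology repair and augmentation                      |
| `touchnet.placement`   | OBJ meshes, voxelization, constrained soma placement    |
| `touchnet.detection`   | voxel rasterization, hypervoxels, touch detection       |
| `touchnet.pruning`     | pruning cascade + analytic expectation oracle           |
| `touchnet.inputs`      | Poisson/correlated trains, input placement, CSV spikes  |
| `touchnet.io`          | JSON network config, HDF5 container, `init` generator   |
| `touchnet.metrics`     | connectivity statistics and ball-and-stick fixtures     |
| `touchnet.pipeline`    | stage runners over a network directory                  |
| `touchnet.cli`         | command-line interface                                  |

Internally everything is SI (metres, seconds, siemens); SWC files on disk
are in micrometres as usual.

## CLI

```sh
touchnet init mysim --size 10062 --seed 1   # config + cube sized to N neurons
touchnet place mysim                        # soma placement (d_min, padding)
touchnet detect mysim                       # putative synapses + gap junctions
touchnet prune mysim                        # apply the pruning cascade
touchnet input mysim --time 5 --input-config mysim/input.json

touchnet morph repair in.swc out.swc --zjump align --cut
touchnet morph modify in.swc out.swc --method twist --amplitude 3.14 --seed 7
```

The network configuration is JSON with blocks `RandomSeed`, `Volume`,
`PopulationUnits`, `Connectivity` (per-pair `pruning` / `pruningOther`
with keys `f1`, `softMax`, `mu2`, `a3`, `distPruning`) and `Neurons`.
Products accumulate in `<dir>/network.hdf5`; every stage is a pure
function of the configuration and its seeds, so reruns are bit-identical.

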