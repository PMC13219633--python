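# lhckit

Comparative structural analysis of photosystem–antenna supercomplexes.

Membrane photosystems such as photosystem I (PSI) are surrounded by
belts of three-transmembrane-helix light-harvesting antenna proteins
(LHC family; called FCPs — fucoxanthin-chlorophyll *a*/*c* proteins —
in red-lineage algae).  Comparing these supercomplexes across organisms
involves three recurring, largely manual analyses that this package
automates and tests end-to-end:

1. **Transmembrane helix heights and membrane rippling.**  Helix
   heights vary from ~48 Å near a photosystem's reaction centre down to
   ~26 Å in outer antenna belts; the resulting *hydrophobic mismatch*
   between neighbouring helices deforms the membrane ("rippling").
   `lhckit` detects helices from Cα geometry, measures each height as a
   curvature-aware piecewise arc length with k ≥ 3 sub-segments, and
   builds the height-binned node/edge graphs used to visualize
   rippling, with per-group mismatch statistics
   Δh = max/mean/min |h_i − h_j| over neighbouring helix pairs.

2. **Chlorophyll distance networks.**  Excitation energy transfer
   (EET) efficiency falls steeply with inter-chlorophyll distance, so
   distance networks are the standard structural proxy.  `lhckit`
   extracts pigments from hetero residues, computes porphyrin
   edge-to-edge distances d_edge = min over heavy-atom pairs of the two
   macrocycles (phytol tails excluded) and Mg–Mg distances, assigns
   stromal/lumenal sides from the membrane frame, builds cutoff
   networks (default d_edge ≤ 15 Å), and after Kabsch superposition
   reports chlorophylls gained/lost between two structures by greedy
   nearest-Mg matching.

3. **Q-score subfamily discrimination.**  The map–model Q-score
   correlates the density around each atom with a reference Gaussian
   g(r) = A·exp(−r²/2σ_ref²) + B (σ_ref = 0.6 Å), giving q ∈ [−1, 1]
   per atom.  Cross-fitting candidate subfamily models into focused
   maps and comparing mean Q discriminates LHC subfamilies (which
   differ most visibly in helix-C length) down to ~5 Å resolution;
   `lhckit` implements density simulation, resolution-aware low-pass
   filtering, bounded rigid-body refinement, the cross-fit matrix and
   the ambiguity-margin report.

A first-class synthetic-data module generates helical bundles, antenna
rings, placed macrocycles and simulated maps with machine-readable
ground truth, so the whole pipeline is verifiable without downloading
depositions.  See `docs/methods.md` for conventions, parameters and
limitations.

## Worked example

Build a synthetic supercomplex — one 48 Å core bundle ringed by six
31 Å belt bundles, the height contrast typical of a photosystem core
against its first antenna belt — and run the rippling analysis:

```python
from lhckit import assign_helices, build_graph, estimate_frame, \
    filter_transmembrane
from lhckit.membrane_geometry import measure_all
from lhckit.rippling import mismatch_between
from lhckit.synthetic_data import core_belt_scene, make_scene

model, truth, annotation = make_scene(core_belt_scene())
helices = assign_helices(model)
frame = estimate_frame(model, helices, explicit_normal=[0, 0, 1])
tm = filter_transmembrane(helices, frame)
measures = measure_all(tm, frame, annotation=annotation)
for m in sorted(measures, key=lambda m: m.subunit_label):
    print(f"{m.subunit_label:>6}: height {m.height:6.2f} A  "
          f"(projected {m.height_projected:6.2f} A)")
graph = build_graph(measures, frame, neighbor_cutoff=30.0)
belts = {f"belt{k}" for k in range(1, 7)}
print("max core-belt mismatch:",
      round(mismatch_between(graph, {"core"}, belts, "max"), 2), "A")
```

prints

```
 belt1: height  31.00 A  (projected  31.00 A)
 belt2: height  31.00 A  (projected  31.00 A)
 belt3: height  31.00 A  (projected  31.00 A)
 belt4: height  31.00 A  (projected  31.00 A)
 belt5: height  31.00 A  (projected  31.00 A)
 belt6: height  31.00 A  (projected  31.00 A)
  core: height  48.00 A  (projected  48.00 A)
max core-belt mismatch: 17.0 A
```

Each height is measured from the detected helix (not read from the
generator): the pipeline recovers the prescribed 48/31 Å heights to
better than 0.01 Å, and the maximum core-to-belt height difference —
the hydrophobic mismatch a first antenna belt must accommodate — is
17 Å.  On real structures the same flow starts from
`read_structure("model.cif")` plus a chain annotation table
(`chain_id, subunit_label, role, subfamily`).

## Command line

The `lhckit` command exposes the same stages for shell use:

```
lhckit synth    --seed 3 --out scene/          # ground-truth fixture
lhckit heights  --structure scene/scene.pdb --annotation scene/annotation.csv \
                --normal 0 0 1 --out out/      # helix-height CSV + frame JSON
lhckit ripple   --structure ... --groups core belt1,belt2 --out out/
lhckit chroma   --structure ... --compare-to other.cif --pairing A:A --out out/
lhckit qscore   --map m1.mrc --model cand1.pdb --model cand2.pdb --out out/
lhckit defaults                                # print every tunable default
```

Exit codes: 0 success, 2 input error, 3 computation error.  Every run
writes a `run_config.json` provenance record.

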