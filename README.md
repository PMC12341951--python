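# ldbind

Analysis toolkit for studying how peripheral proteins recognise the surface
of a **lipid droplet (LD) monolayer** versus an ordinary **ER bilayer**.
Lipid droplets are bounded by a single phospholipid leaflet stretched over a
neutral-lipid core (wax esters or triacylglycerols), and LD-associated
proteins such as the plant LDAPs discriminate that surface from bilayers
through loop insertion, packing defects and amphipathic-helix chemistry.
`ldbind` implements the standard computational read-outs of that problem for
membrane-biophysics and structural-bioinformatics users:

- **Per-residue contact numbers.** For residue *i* at frame *t*,
  `C_i(t) = Σ_{a∈i, b∈membrane} 1 / (1 + e^{5(d_ab − 4)})` over heavy-atom
  pairs within a 5 Å prefilter (*d* in Å, minimum image in x,y). A residue is
  in a *bound conformation* when `C_i(t) > 25`; per-residue averages over
  bound frames are reported as a cumulative sum over residue index.
- **Penetration-depth maps.** Per-residue histograms of
  `|z_i − z_center|`, max-normalised per residue (`P_i(z)/P_i(max)`), so
  each row peaks at 1 and rows are directly comparable.
- **Packing defects.** A grid scan of a leaflet surface: a cell is a defect
  when no lipid/core atom in it reaches above the glycerol plane; 4-connected
  components give defect areas, summarised by the exponential size constant
  λ of `P(area) ∝ e^{−area/λ}`.
- **Amphipathic-helix analytics.** Helical-wheel projection (100°/residue),
  Wimley–White interfacial hydrophobicity sums (negative = hydrophobic),
  Eisenberg-style hydrophobic moment, point mutations (`F159I`, `M161L`, …),
  backbone φ/ψ dihedrals and helicity calls against the canonical
  (−57°, −47°).
- **A synthetic trajectory generator** that emulates the study design at
  bead resolution: planar bilayer / WE-filled / TAG-filled monolayer patches
  with jojoba-like (PC:PE:PI:PG = 45:38:10:7) or tobacco-like
  (PC:PE:PA:PG:PI:PS = 60:59:37:26:15:3) headgroup compositions, a rigid
  pseudo-protein placed 50 Å above the membrane centre in one of 6 canonical
  orientations, scripted approach/insertion/bounce kinematics, and Poisson
  surfacing of core lipids that opens packing defects. Everything is seeded
  and bit-reproducible, so analyses can be validated against known ground
  truth.

## Worked example

Generate a WE-filled-monolayer binding scenario whose ground truth inserts
loop residues 40–45 after 30 ns, then recover that loop from the contact and
depth stages:

```python
import numpy as np
from ldbind import (ScenarioConfig, generate_trajectory, contact_profile,
                    membrane_geometry, depth_map)

cfg = ScenarioConfig(membrane_kind="we_monolayer", n_frames=100,
                     bind_time=30.0, seed=7, surfacing_rate=0.5)
traj = generate_trajectory(cfg)

prof = contact_profile(traj)                 # sigmoid contacts, >25 criterion
print("bound residues:", prof.bound_residues().tolist())
print("first binding frame:", prof.first_binding_frame)

geo = membrane_geometry(traj)
dmap = depth_map(traj, geo, z_max=90.0)
i = list(dmap.residue_ids).index(42)
print("modal depth residue 42: %.1f A" % dmap.modal_depth()[i])
print("head-plane depth: %.1f A" % np.mean(geo.head_plane_upper - geo.center_z))
```

prints

```
bound residues: [40, 41, 42, 43, 44, 45]
first binding frame: 33
modal depth residue 42: 28.5 A
head-plane depth: 34.0 A
```

Exactly the scripted loop is called bound (no false positives), binding
begins shortly after the scripted 30 ns, and the loop's modal depth
(28.5 Å from the membrane centre) lies below the headgroup plane (34.0 Å) —
i.e. the residues are inserted into the monolayer.

Helix chemistry from the command line — the Arabidopsis-to-jojoba double
swap makes the helix-6 window more interface-hydrophobic by
(WW[F]−WW[I]) + (WW[L]−WW[M]) = −1.15 kcal/mol, independent of the
surrounding sequence:

```sh
ldbind helix --sequence GGGIGGMGG --range 156:164 --seq-offset 156 \
             --mutate I159F --mutate M162L
```

Full pipelines (`simulate → contacts → depth → defects → helix`) run from a
YAML config via `ldbind run --config pipeline.yaml --out report/`, and
`ldbind compare` tabulates headline metrics across scenario factors
(membrane core, composition, orientation).

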