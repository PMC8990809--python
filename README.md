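# pipsites

Mapping where phosphoinositide (PIP) headgroups bind C_n-symmetric
membrane proteins — such as the tetrameric HCN pacemaker channels — from
two complementary kinds of evidence:

1. **Docked headgroup poses.** Docking a PIP headgroup (truncated at the
   glycerol C1 carbon) hundreds of times against a membrane-oriented
   structure yields a cloud of poses that must be filtered and condensed
   before it says anything about binding sites.
2. **Coarse-grained trajectories.** Simulations of the protein in a
   PIP-containing bilayer yield lipid–residue contact time series from
   which occupancies, residence times and binding sites are derived.

`pipsites` implements the post-processing for both, plus deterministic
synthetic fixtures (toy C4 tetramers, planted pose clusters, scripted
lipid dwells) so the whole stack is testable without external data.

## The analyses

**Pose vectors.** Each docked headgroup is reduced to three centroids:
the glycerol C1 carbon, the inositol ring, and an anchor phosphate at the
3/4/5 position (for unphosphorylated PI, the C4 hydroxyl oxygen). With
the membrane normal along +z, the tail direction **t** = C1 − inositol
has elevation φ = asin(t_z/|t|); a pose is *accepted* when the tail is
parallel to the membrane plane or points toward the bilayer
(φ ≥ −tolerance, default 15°). Accepted poses are rotated by multiples of
360°/n about the symmetry axis into a reference wedge, so the n
symmetry-equivalent copies of each site superimpose.

**Pose clustering.** Accepted, wedge-reduced poses are clustered by
single linkage: two poses are linked when their centroids are within
15 Å of one another (by default all three centroid pairs must be; an
inositol-only mode is available). Each cluster's representative is the
medoid on the inositol centroid. Residues with a heavy atom within 4 Å
(inclusive) of any ligand heavy atom are the pose's contacts; per-residue
contact frequency is reported as a percentage of accepted poses.

**Dual-cutoff contacts.** On a trajectory, a lipid–residue contact
starts the first frame the minimum headgroup-bead-to-residue distance
drops to 0.5 nm and persists while it stays within 0.8 nm. Occupancy is
the percentage of frames a residue (or site) is contacted by ≥1 lipid;
residence times are event durations. Binding sites are found by
commonality: residues simultaneously contacted by the same lipid
molecule in ≥5% of frames are connected, and connected components become
sites. A 2D membrane-plane histogram of bead positions gives the lipid
density map.

## Worked example

Generate fixtures (a C4 toy tetramer, 100 docked poses around two
planted centers with a quarter misoriented, and a scripted dwell
trajectory), then run both workflows:

```sh
pipsites synth --out-dir demo --seed 42
pipsites dock-cluster --config demo/config_dock.yaml --out-dir demo/dock
pipsites traj-occupancy --config demo/config_traj.yaml --out-dir demo/traj
```

`demo/dock/summary.json`:

```json
{
  "acceptance_fraction": 0.75,
  "n_accepted": 75,
  "n_clusters": 2,
  "n_distinct_residues": 4,
  "n_poses_total": 100,
  "species": "PI45P2",
  "state_label": ""
}
```

75 of 100 poses pass the orientation filter (25 were planted tail-down),
and they fall into the two planted clusters. The contact table
(`contact_frequencies.csv`) shows the basic residues facing the planted
site:

```
chain_id,residue_number,residue_name,n_poses,frequency_pct
B,2,ARG,34,45.333333
B,1,LYS,30,40.000000
B,3,SER,2,2.666667
B,4,LEU,1,1.333333
```

The trajectory workflow recovers the two planted binding sites with
their scripted occupancies (`demo/traj/sites.csv`):

```
site_id,occupancy_pct,n_residues,residues
1,100.000000,4,A:1;A:2;A:7;A:8
2,40.000000,3,B:1;B:2;B:7
```

The same pipelines run on real inputs: a membrane-oriented PDB
structure, AutoDock multi-MODEL PDB/PDBQT pose files, and multi-MODEL
PDB or GRO+XTC trajectories.

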