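# cardkit

Interface interaction, persistence and consensus-docking analysis for
CARD-domain protein complexes.

CARD (caspase activation and recruitment domain) modules drive the assembly
of apoptotic signalling platforms: in the apoptosome, the Apaf-1 CARD
(ApCARD) recruits and activates procaspase-9 through a conserved CARD–CARD
contact. Characterising that contact computationally means answering three
questions over and over: *which* typed residue–residue interactions
(hydrogen bonds, salt bridges, hydrophobic contacts, π-cation pairs) hold
an interface together and how persistently; *how large and how charged* the
buried interface is; and *which docked pose* of a complex to trust when
several docking engines disagree. cardkit packages those analyses as a
tested Python library with a thin CLI, for structural bioinformaticians who
have trajectories (multi-model PDB), docked pose ensembles and reference
crystal complexes and want reproducible, diffable tables out.

## What it computes

- **Typed interaction detection** between two chain groups per frame, with
  configurable geometric criteria, plus persistence fractions (percentage
  of frames; summed over types a pair may exceed 100%), type-over-time
  heatmaps, per-residue accumulated counts with the >10%-of-frames display
  filter, and the >5-accumulated-interactions key-residue rule.
- **Native-interaction percentage** per frame against the residue pairs of
  a reference complex — pairwise for native complexes, one-sided for
  cross-docked ones.
- **RMSD to the first frame** (Kabsch superposition, backbone by default)
  and fixed-interval (3 ns) series sampling.
- **Buried interface area** sasaA + sasaB − sasaAB from a deterministic
  Shrake–Rupley implementation (both halved and raw conventions), and
  Coulombic surface potential φ = k·Σ qᵢ/(ε·dᵢ) in kcal/(mol·e) at
  solvent-accessible surface points.
- **Consensus docking**: pool top poses from several engines, cluster by
  pairwise heavy-atom RMSD, select the cluster count with the
  Kelley–Gardner–Sutcliffe penalty, report the medoid of the largest
  cluster as the representative complex.
- **Routed statistics**: consensus normality (Lilliefors-corrected KS +
  Shapiro–Wilk + Anderson–Darling, all must agree) routing to Welch's
  t test or the Mann–Whitney U test.
- **Synthetic complexes** with planted, verifiable ground truth — dimers
  with planted contacts of every type, trajectories with programmed
  contact schedules, pose ensembles with known cluster structure — so the
  whole pipeline is testable without downloads.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Generate a synthetic demo dataset (a two-chain complex with five planted
contacts, a 12-frame trajectory, five engines × poses from 3 planted
clusters) and run the three workflows:

```sh
cardkit simulate --out demo --seed 5 --n-frames 12
cardkit characterize --trajectory demo/trajectory.pdb --reference demo/dimer.pdb \
        --group-a A --group-b B --dt-ns 3 --out runs/char
cardkit interface  --structure demo/dimer.pdb --group-a A --group-b B --out runs/iface
cardkit consensus  --poses demo/poses/engineA.pdb --poses demo/poses/engineB.pdb \
        --poses demo/poses/engineC.pdb --poses demo/poses/engineD.pdb \
        --poses demo/poses/engineE.pdb --out runs/cons
```

The interface step prints

```
buried interface area: 150.05 Å² (half-sum), 300.10 Å² (full-sum)
```

— the area buried on complexation under both conventions (one face's
worth, and both faces summed). `runs/char/summary.json` then reports

```json
{
  "n_frames": 12,
  "n_records": 69,
  "native_fraction_mean_pct": 92.0,
  "rmsd_mean_A": 0.0007,
  ...
}
```

69 typed interaction records were detected across 12 frames; on average
92% of the native (reference-complex) residue pairs are present per frame
— the planted contacts flicker with the programmed 0.9 presence
probability — and the backbone RMSD to frame 0 is ~0 Å because the demo
trajectory only applies whole-complex rigid jitter. The consensus step
prints the Kelley-selected cluster count and the representative pose index,
with the penalty curve and labels written as CSV.

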