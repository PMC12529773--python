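# ncitraj

Residue-resolved noncovalent-interaction (NCI) analysis of molecular-dynamics
protein-folding trajectories.

`ncitraj` decomposes what happens during a folding or unfolding event into
*which residue pairs* interact, *through which interaction channel*
(attractive, van der Waals, repulsive), and *in what order*. It combines:

1. a **promolecular NCI engine** — electron density approximated as a sum of
   exponential atomic densities, the reduced density gradient
   s = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3}) locating noncovalent interaction
   regions, and sign(λ₂)ρ (λ₂ = middle Hessian eigenvalue of ρ) splitting
   them into attractive / van der Waals / repulsive channels;
2. **per-residue-pair channel integrals** on an adaptively refined voxel
   grid, giving a 3-channel time series for every residue pair along a
   trajectory;
3. a **folding order parameter** Q (soft-switch fraction of native contacts)
   with last-exit/first-entry transition detection that excludes recrossings;
4. **motif and pathway clustering** — residue pairs that form together are
   grouped into motifs (one global assignment, so motif identities are
   comparable across events), each transition is summarized by per-motif
   formation profiles, and transitions are clustered into pathways.

Supporting tools: geometric hydrogen-bond detection, Shrake–Rupley SASA,
ensemble contact maps and difference maps, cube-file I/O, and synthetic
fixture generators (hydrogen-bond dimer, apolar dimer, and a toy folding
trajectory with planted pathways) used throughout the tests.

See `docs/methods.md` for the model, all numerical parameters, and the
limitations.

## Worked example 1: a hydrogen bond vs. an apolar contact

```bash
$ ncitraj fixtures --kind hbond --out dimer.pdb
wrote dimer.pdb (1 frames, 7 atoms)
wrote dimer.json

$ ncitraj hbonds dimer.pdb
A:RES1 -> A:RES5  H..A 1.89 A  angle 180.0 deg
1 hydrogen bonds

$ ncitraj integrate dimer.pdb --spacing 0.1
 frame   resi   resj  attractive      vdw  repulsive    total
     0 A:RES1 A:RES5    0.036076 0.012851        0.0 0.048928
```

The N–H···O dimer (N···O 2.9 Å) puts most of its interaction density in the
attractive channel (0.0361 of 0.0489 total). The same calculation on two
methane molecules at van der Waals contact gives an attractive integral of
0.0021 — 1.2 % of its total — and exactly 0 at a relaxed 4.0 Å separation:
the channels discriminate hydrogen bonding from dispersion contact.

## Worked example 2: recovering planted folding pathways

The toy trajectory has 8 pseudo-residues and two programmed formation orders:
pathway 0 forms motif A (pairs 1–5, 2–6) before motif B (3–7, 4–8); pathway 1
forms B before A. 20 events are planted with a 60/40 mix.

```bash
$ ncitraj fixtures --kind toy --n-events 20 --seed 11 --out toy20.pdb
wrote toy20.pdb (1530 frames, 24 atoms)
wrote toy20.json

$ python -c "
from ncitraj.grid_engine import NCIParams
from ncitraj.workflow import RunConfig, save_config
save_config(RunConfig(nci=NCIParams(spacing=0.3), seed=11), 'config.yaml')"

$ ncitraj run-all toy20.pdb --config config.yaml --reference-frame 69 --out run
{
  "transitions": 20,
  "motifs": 2,
  "pathways": 2,
  "pathway_fractions": {
    "0": 0.6,
    "1": 0.4
  },
  "out_dir": ".../run"
}
```

(`--reference-frame 69` points at a folded frame — the native reference for
Q; the trajectory starts unfolded.) The run takes about 6 minutes on one CPU
and writes `q_series.csv`, `transitions.csv`, `summary.json` and the config
with its hash into `run/`. Checking `transitions.csv` against the planted
assignment gives 20/20 event-membership agreement, and the recovered motifs
are the planted ones (motif 0 = pairs 1–5, 2–6; motif 1 = 3–7, 4–8 plus the
adjacent transient 3–8). Pathway-0 events form motif 0 first, pathway-1
events form motif 1 first, matching the construction.

Results are deterministic: rerunning with the same config and seed produces
byte-identical CSV/JSON outputs. With only a handful of events the transition
clustering is under-determined and can split spuriously (e.g. 4 events often
yield 3 "pathways"); pathway statistics need on the order of 10+ events.

## CLI overview

| command | purpose |
|---|---|
| `ncitraj fragment / pairs` | list residue fragments and analyzed pairs |
| `ncitraj q / transitions` | fraction-of-native-contacts series, transition detection |
| `ncitraj integrate` | per-pair NCI channel integrals for one frame |
| `ncitraj hbonds / sasa` | hydrogen bonds, solvent-accessible surface area |
| `ncitraj run-all` | full pipeline: Q → transitions → integrals → motifs → pathways |
| `ncitraj fixtures` | generate the synthetic test systems |
| `ncitraj config-init` | write a default YAML configuration |

The same functionality is available as a library (`import ncitraj`).

## Reproduction

```bash
python -m pytest -q tests/                       # full suite, ~7 min on 1 CPU
python scripts/acceptance.py --seed 123 --out results/acceptance.json
```

The test suite checks the analytic oracles (closed-form reduced density
gradient and Hessian eigenvalues; finite-difference derivatives to < 1e-5),
exact channel partitioning, grid convergence (0.1 vs 0.05 bohr within 2 %),
rigid-motion invariance (< 1 %), transition detection against a brute-force
reference, hydrogen-bond geometry cuts, a SASA sphere oracle, the end-to-end
pathway recovery above, and byte-identical determinism of `run-all`.
`scripts/acceptance.py` recomputes the headline numbers from scratch
(~8 minutes) and writes them as JSON; with `--seed 123` it reports, among
others, `hbond_attractive_integral` 0.036076, `rigid_motion_max_change_pct`
0.131, `toy_pathway_agreement` 1.0 and `toy_major_pathway_fraction` 0.6.

All inputs are generated programmatically; no external data sets are
required or downloaded.
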