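# plihub

Whole-brain **hub analysis of resting-state EEG**: phase-lag-index (PLI)
functional connectivity, inverse-PLI weighted graphs, normalized
betweenness-centrality (BC) hub profiles per electrode, and the
group/treatment statistics used to compare them — plus a synthetic
oscillator-cohort generator that makes every stage of the pipeline
verifiable against planted ground truth.

It is aimed at clinical-EEG researchers who ask questions like *"which
electrodes act as network hubs in each frequency band, and does hub status
differ between patients and controls or change with treatment?"* on
standard 10-20 recordings (16 channels, 200 Hz).

## The method

For each subject and frequency band (delta 2–4, theta 4–8, alpha 8–13,
beta 13–30, gamma 30–60 Hz):

1. **Filtering & epoching.** The continuous record is bandpass filtered
   with a 4000th-order linear-phase FIR (Hamming window), cut into 5-s
   epochs, and the first and last epochs are dropped. A 600-s record yields
   118 analysis epochs.
2. **PLI connectivity.** Per epoch, instantaneous phases come from the
   Hilbert transform, and for every electrode pair

   PLI = | (1/T) Σₖ sign Δφ(tₖ) |,  Δφ wrapped to the principal interval,

   which is 0 for absent *or zero-lag* coupling (so instantaneous
   volume-conduction of a common source is discounted) and 1 for perfect
   fixed-lag coupling. Epoch values are averaged into one 16×16 matrix.
3. **Hub profiles.** The matrix defines a weighted graph with edge length
   1/PLI; normalized betweenness centrality

   bᵢ = [Σ_{h≠j≠i} ρ_hj(i)/ρ_hj] / ((n−1)(n−2))

   is computed per electrode on the whole graph (no minimum-spanning-tree
   pruning), with fractional credit across co-minimal shortest paths.
4. **Statistics.** Per band, a mixed repeated-measures ANOVA
   (group × node) with Greenhouse–Geisser correction gates per-electrode
   post hoc t-tests under Benjamini–Hochberg FDR (q < 0.05); a two-way
   within-subject ANOVA handles pre/post-treatment designs; Pearson
   correlations relate hub BC to clinical score (BPRS) and age.

The synthetic generator plants band-specific hubs by injecting a hub
channel's narrowband oscillation into target channels at a fixed nonzero
lag, on top of wandering-phase background oscillators, a zero-lag common
source and 1/f noise — so hub recovery, false-positive calibration and
volume-conduction insensitivity can all be measured.

## Worked example

```python
from plihub import CohortConfig, generate_cohort
from plihub.pipeline import (cohort_connectivity, cohort_bc_tables,
                             group_comparison_stats)

cfg = CohortConfig(n_per_group={"control": 15, "patient": 15},
                   duration_s=60, seed=1)   # default planted-hub scenario
recs, metas = generate_cohort(cfg)
conn = cohort_connectivity(recs)            # per band, per subject 16x16 PLI
bc, _ = cohort_bc_tables(conn)              # per band subjects x 16 BC table
st = group_comparison_stats(bc, metas, list(recs[0].montage.labels))
print("gated bands:", st.gated_bands)
for r in st.posthoc:
    if r.significant:
        print(f"{r.band:6s} {r.electrode:3s} t={r.t:7.2f} q={r.q_bh:.4f} "
              f"dir={'patient>control' if r.direction > 0 else 'patient<control'}")
```

Output:

```
gated bands: ['beta', 'gamma']
beta   F3  t=  -2.86 q=0.0426 dir=patient<control
beta   F4  t=  -2.71 q=0.0450 dir=patient<control
beta   Fz  t= -22.82 q=0.0000 dir=patient<control
beta   T5  t=   3.02 q=0.0423 dir=patient>control
beta   O1  t=   2.59 q=0.0477 dir=patient>control
gamma  C3  t=  -3.57 q=0.0052 dir=patient<control
gamma  C4  t=  -2.69 q=0.0385 dir=patient<control
gamma  Pz  t= -20.09 q=0.0000 dir=patient<control
gamma  T5  t=   4.07 q=0.0018 dir=patient>control
gamma  O1  t=  24.50 q=0.0000 dir=patient>control
```

The three planted contrasts dominate, with their correct directions: hub
coupling (and hence BC) is lower in patients at Fz in the beta band and
at Pz in the gamma band, and higher at O1 in the gamma band. The
secondary hits are genuine signal too: F3/F4 and C3/C4 are targets of
the planted Fz and Pz hubs, and because betweenness is a relative
measure, removing a dominant hub redistributes centrality toward
peripheral electrodes such as T5 and O1.

The same pipeline runs from a shell:

```bash
plihub all --config examples/recovery.yaml --out results/
plihub simulate --config examples/recovery.yaml --out cohort/   # EDF + metadata
plihub stats --config examples/recovery.yaml \
             --bc results/bc.csv --metadata results/metadata.csv --out stats2/
```

Real recordings are accepted as EDF files (one per subject, named
`<subject_id>.edf`) with a `metadata.csv` of columns
`subject_id,group,session,bprs,age`.

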