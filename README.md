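# loopshift

Replica-aware analysis of protein **loop conformational population shifts**
from molecular-dynamics-style coordinate ensembles.

Many enzymes are gated by a mobile loop that interconverts between a
catalytically active *closed* conformation and inactive *open* /
*wide-open* conformations — protein tyrosine phosphatases and their
WPD-loop are the canonical example, where the closed↔wide-open transition
spans ~10 Å and sequence changes on the loop can shift the population
balance between these states. `loopshift` provides the statistical
machinery to quantify such shifts from multi-replica ensembles and to trace
them to their molecular causes:

- **State classification** — per-frame loop Cα-RMSD to closed/open/wide-open
  reference structures (superposing on the non-loop scaffold), argmin +
  threshold labeling into `{closed, open, wide_open, other}`, population
  histograms (0.16 Å bins), cutoff fractions, and per-state populations with
  between-replica standard errors.
- **Flexibility statistics** — per-replica, per-residue Cα RMSF; ΔRMSF
  between variants; two-sided t-tests with the *replicas* (not frames) as
  the statistical unit; Benjamini–Hochberg control at a 5% false discovery
  rate; projection of significant ΔRMSF onto a structure's B-factor column.
- **Interaction networks** — geometric hydrogen-bond / salt-bridge /
  contact detection, state-conditioned occupancies, and ranked occupancy
  differences between variants (keys join by residue *position*, so
  chimeric substitutions compare cleanly).
- **Reaction energetics** — a two-state empirical valence bond (EVB)
  estimator: Zwanzig free-energy ladder over a 51-window mapping potential
  `E_m = (1−λ)E1 + λ(E2+α)`, umbrella reconstruction of the ground-state
  profile Δg(x) along the energy gap `x = E1 − E2′`, ΔG‡ and ΔG⁰
  extraction, and linear-response (LRA) per-residue electrostatic
  contributions `ΔΔG‡ = ½(⟨Δu⟩_RS + ⟨Δu⟩_TS)/ε_in` with ε_in = 4.
- **Synthetic data** — a Markov-chain + Gaussian-noise ensemble generator
  with exact ground truth (true labels, closed-form stationary
  distributions, planted flexibility/interaction effects, harmonic diabats
  with an analytic barrier oracle), so every stage is testable end to end.

## Worked example

Compare two variants with planted wide-open stationary probabilities 0.7
vs 0.3 (quick preset: 3 replicas × 500 frames):

```python
from loopshift.pipeline import build_variant_spec, run_variant, compare_variants

spec_a = build_variant_spec({"stationary": [0.2, 0.1, 0.7]}, preset="quick", seed=1)
spec_b = build_variant_spec({"stationary": [0.6, 0.1, 0.3]}, preset="quick", seed=2)
rep = compare_variants(run_variant(spec_a, "chimera2_like"),
                       run_variant(spec_b, "chimera3_like"))
print(rep.populations.round(4).to_string(index=False))
```

```
      variant     state  fraction     se   lo3se  hi3se
chimera2_like    closed    0.1227 0.0838 -0.1288 0.3741
chimera2_like      open    0.1687 0.0260  0.0907 0.2466
chimera2_like wide_open    0.7087 0.1005  0.4073 1.0101
chimera2_like     other    0.0000 0.0000  0.0000 0.0000
chimera3_like    closed    0.5613 0.0849  0.3065 0.8161
chimera3_like      open    0.1187 0.0617 -0.0665 0.3039
chimera3_like wide_open    0.3200 0.0321  0.2238 0.4162
chimera3_like     other    0.0000 0.0000  0.0000 0.0000
```

Each row is a state's occupancy fraction with its between-replica standard
error and a 3-SE interval; here the planted wide-open shift (0.71 vs 0.32)
is recovered, and at the full study scale (15 × 5,000 frames) the 3-SE
intervals separate cleanly. `rep.rmsf_report.table` holds the per-residue
ΔRMSF significance table for the same pair.

The CLI drives the same stages from a YAML config:

```bash
loopshift run --config config.yaml --outdir out --seed 1
loopshift states --config config.yaml       # simulate + label + histograms
loopshift evb-map --config config.yaml      # EVB ladder + free-energy profile
```

Every table is written as TSV next to a JSON run report; identical
(config, seed) pairs reproduce all tables byte-for-byte.

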