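# pxrfkit

Portable X-ray fluorescence (pXRF) lets biologists measure elemental
composition of animal samples quickly and non-destructively — but the
numbers an instrument reports depend on how the sample was presented:
whether it was thawed or dried, where on the body it was scanned, how long
each beam dwelt on it, and whether the sample was thick enough that no
X-rays escaped through it ("infinite thickness"). `pxrfkit` is a complete,
tested pipeline for studies of those sources of variation: it simulates
instrument scan exports with known ground truth, processes raw beam
spectra, screens reported elements against their diagnostic emission
lines, decides infinite thickness from the tungsten tube-scatter lines,
and runs the statistical battery that such studies use.

**What's inside**

| stage | method |
|---|---|
| `simulate` | seeded factorial study generator: 2048-channel beam spectra (Gaussian lines + continuum + Poisson), moisture/thickness/drying effects, 42-element concentration tables with LOD censoring |
| `io_vanta` | documented JSON export dialect (schema in `schema/scan_export.json`), validation, long-format CSV compilation |
| `spectra` | energy calibration, Gaussian smoothing, SNIP baseline clipping, peak-window sums |
| `validation` | element presence screening via Kα1 + Kβ peaks at SNR ≥ 3 in 80 s scans; LOD filtering |
| `thickness` | backed-vs-unbacked tungsten L-line comparison, `rel_diff ≤ 0.10` per line |
| `stats` | median (τ=0.5) quantile regression with permutation inference; overall sum-of-likelihood-ratio multi-response test (Freedman–Lane row permutation); Spearman replicate precision |
| `pipeline` / CLI | one reproducible run: ingest → QC → tests → summary, with config-hash + seed provenance on every output |

The statistical core in the field's notation: per element the two-group
median quantile regression minimises Σ|yᵢ − (β₀ + β₁·𝟙[gᵢ=2])|/2, whose fit
is (median₁, median₂ − median₁); inference permutes group labels on
|β̂₁| with p = (1 + #{perm ≥ obs})/(B + 1). The overall test fits one
Gaussian GLM per element on log-transformed concentrations and sums
per-element likelihood ratios LRⱼ = n·ln(RSS₀ⱼ/RSS₁ⱼ) across elements,
with significance by joint row permutation — the "manyglm" style of
multi-response testing. Replicate precision is Spearman's ρ on duplicate
scans.

## Worked example

Simulate a compact study (2 specimens each of fish and bird feathers, 20 s
and 80 s dwell times, backed and unbacked, duplicate scans), then run the
full analysis:

```bash
cat > study.yaml <<EOF
n_specimens: 2
taxa: [fish, bird]
dwell_times: [20.0, 80.0]
EOF
pxrfkit simulate --config study.yaml --seed 7 --out exports/
# wrote 128 exports to exports/
pxrfkit run --in exports/ --out run/ --n-perm 199 --seed 1
pxrfkit report --in run/
```

which prints:

```
taxon       state  state_n_sig_elements   scan_time  scan_time_n_sig_elements location  location_n_sig_elements infinite_thickness  replicate_spearman
 bird         NaN                     0 significant                        10       ns                        0            not met               0.999
 fish significant                    28 significant                        25       ns                        0                met               0.999
```

Reading the matrix: the generator applies a ×1.4 drying effect, so the
fish state test is significant overall with many per-element hits (birds
have no state test — feathers are only scanned in their natural state);
20 s scans differ measurably from 80 s scans for both taxa (the generator's
short-scan bias); scan locations were simulated identically, so the
location tests are correctly non-significant; feathers are thin and fail
infinite-thickness QC while fish carcasses pass; and duplicate scans
correlate at Spearman ρ = 0.999. Full per-comparison tables
(`results_state.csv`, `results_scan_time.csv`, `results_location.csv`),
the screening evidence, thickness verdicts and per-element precision live
in `run/`.

Everything is also available as a library:

```python
from pxrfkit import simulate, stats

cfg = simulate.default_config(n_specimens=10, taxa=("mammal",), seed=0)
table = simulate.simulate_concentration_table(cfg)   # fast path, no spectra
res = stats.median_permutation_test(
    table[table.element == "Fe"]["concentration_pct"],
    table[table.element == "Fe"]["state"],
    n_perm=999, seed=1,
)
print(res.estimate, res.p_value)
```

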