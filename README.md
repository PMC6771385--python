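# pauseflux

Kinetic modeling of RNA polymerase II promoter-proximal pausing, for
people analyzing nascent-transcription (PRO-seq-style) data who want to
reason from observed pause/gene-body density changes back to mechanism.

After initiating, Pol II pauses ~30–60 bp downstream of the TSS before
either releasing productively into the gene body or dissociating
non-productively. A perturbation (for example, rapid depletion of a
transcription factor) changes the read densities in the pause region and
gene body — but several different rate changes could produce any given
pattern. `pauseflux` encodes the minimal two-compartment model that makes
this reasoning precise, and a synthetic-data pipeline to validate it.

## The model

Pause-region density `p` and gene-body density `b` (Pol II per bp) follow

```
dp/dt = k_init − (k_pre + k_rel) p
db/dt = (l_p/l_b) k_rel p − k_term b
```

with rate constants for initiation (`k_init`), premature pause release
(`k_pre`), productive release into elongation (`k_rel`), and termination
(`k_term`); `l_p`/`l_b` are the pause/body lengths. Steady states are
closed-form:

```
p_ss = k_init/(k_pre + k_rel),   b_ss = (l_p/l_b) k_rel p_ss / k_term,
P_i  = p_ss/b_ss = k_term l_b / (k_rel l_p)
```

The pause index `P_i` is blind to `k_init` and `k_pre`; for a change in
either, the effect ratio `Δp/Δb` equals `P_i` exactly, and since
`l_b/l_p ≈ 100` the pause region responds far more strongly than the
body. A coordinate decrease of both densities with an unchanged pause
index therefore implicates reduced initiation or increased premature
release — the two are not separable from densities alone.

## Worked example

```python
import pauseflux as pf

p = pf.RateParams(k_init=1.0, k_pre=0.5, k_rel=0.5, k_term=1.0, l_p=100, l_b=10_000)
ss = pf.steady_state(p)
print(ss.p_ss, ss.b_ss, ss.pause_index)
# 1.0 0.005 200.0

up = pf.steady_state(p.perturb("k_init", 1.25))
print(up.p_ss, up.b_ss, up.pause_index)
# 1.25 0.00625 200.0          <- both densities +25%, pause index unchanged

print(pf.delta_p(p, "k_pre", 0.8, 0.5), pf.delta_b(p, "k_pre", 0.8, 0.5))
# -0.23076923076923078 -0.001153846153846154
print(pf.effect_ratio(p, "k_pre", 0.8, 0.5).ratio)
# 200.0                       <- Δp/Δb equals the pause index exactly
```

A 25% initiation increase scales both compartments by exactly 1.25; a 60%
increase of premature release (`k_pre` 0.5→0.8) drops the pause density by
0.231 and the body density by 0.00115 — a 200-fold larger absolute effect
on the pause, matching `P_i`.

The synthetic pipeline closes the loop from tracks back to mechanism:

```python
from pauseflux.synthetic import SyntheticConfig, generate_dataset
from pauseflux.quantify import summarize, compare_conditions
from pauseflux.inference import classify_table

cfg = SyntheticConfig(seed=1)          # 200 genes, 30% targets, k_pre x1.6, depth 100
ds = generate_dataset(cfg)
fc = compare_conditions(
    summarize(ds.tracks["A"], ds.genes, "A", scale="none"),
    summarize(ds.tracks["B"], ds.genes, "B", scale="none"),
)
calls = classify_table(fc)
t = fc["is_target"]
print((calls.loc[t.values, "call"] == "init_down_or_pre_up").mean())
# 1.0                         <- all 57 target genes called correctly
```

Or from the shell:

```
pauseflux run --seed 1 --outdir out/ --scale none
pauseflux profile --params params.json --perturb k_init:1.25 --perturb k_pre:1.6 --out profile.tsv
pauseflux fit-decay --input out/timecourse.tsv --out fit.json
```

`pauseflux run` writes `genes.bed`, strand-specific bedGraph tracks for
both conditions, `densities.tsv`, `foldchange.tsv`, `mechanisms.tsv`, and
a `provenance.json` recording the config and seed. The decay fitter
recovers `k = 0.02/min` (half-life 34.657 min) to machine precision from
a noiseless 17-point time course.

See `docs/methods.md` for the model's assumptions, the generator's scope,
and all numerical choices.

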