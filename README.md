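# kerastate

Donor-paired single-cell analysis of keratinocyte marker expression, built
around one question: when the fraction of marker-positive keratinocytes
differs between two conditions of the same donors' skin (for example the
normal and lymphedema-affected limbs of breast-cancer-related-lymphedema
patients, with F2RL1/PAR2 as the marker), how much of that difference comes
from keratinocytes *changing expression within their states*, and how much
from the tissue *changing its mix of states*?

## The statistic

For condition *c*, write the overall marker-positive fraction over
keratinocyte states *s* as

    P^c = Σ_s π_s^c · p_s^c

where π_s^c is the proportion of keratinocytes in state *s* and p_s^c the
fraction of state-*s* cells with raw marker UMI > 0. The package splits
ΔP = P^B − P^A exactly into

    within      = Σ_s π̄_s (p_s^B − p_s^A)        π̄_s = (π_s^A + π_s^B)/2
    composition = Σ_s p̄_s (π_s^B − π_s^A)        p̄_s = (p_s^A + p_s^B)/2

the symmetric (Kitagawa) two-fold decomposition: `within + composition =
ΔP` holds to machine precision, and swapping conditions negates all three
terms. Donor-level inference uses a paired Student t-test on per-donor
fractions.

Around this core the package provides the full estimation pipeline —
four-filter QC (≥200 genes, ≥500 UMIs, ≤50% ribosomal, ≤20% mitochondrial
per cell), log-normalization (counts-per-10k), 3000 highly variable genes,
30 principal components, donor batch-centering, Leiden clustering
(resolution 0.5), marker-score keratinocyte annotation, and sub-state
assignment — plus a negative-binomial synthetic cohort generator whose
analytic ground truth validates the whole chain, and a small morphometrics
module implementing the truncated-cone tail-volume estimator
V = h/(4π)·(C1C2 + C2C3 + C3C4) used for rodent swelling curves.

## Worked example

```python
from kerastate import synthetic as syn
from kerastate.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(cohort=syn.default_config(), seed=1))
pooled = report["decomposition"]["pooled"]
print(f"P(normal) = {100 * report['pooled_fraction_a']:.1f}%")
print(f"P(LE)     = {100 * report['pooled_fraction_b']:.1f}%")
print(f"within    = {pooled['within_pp']:.2f} pp")
print(f"composition = {pooled['composition_pp']:.2f} pp")
print(f"paired t p  = {report['paired_test']['p_value']:.3f}")
print(f"sub-state ARI vs truth = {report['recovery']['substate_ari']:.2f}")
```

prints (seed 1):

```
P(normal) = 40.9%
P(LE)     = 37.6%
within    = -2.27 pp
composition = -1.04 pp
paired t p  = 0.017
sub-state ARI vs truth = 1.00
```

The default cohort simulates 3 donors × 2 conditions × 1500 cells with
four keratinocyte states (basal K0, differentiating K3, proliferative K6,
stress-response K8) and one immune-like population. Its *analytic* truth is
an overall drop from 41.6% to 36.4% marker-positive split into −4.62 pp
within-state and −0.62 pp compositional; a single 3-donor realization
scatters around those values (as above), and the estimates converge to them
as donors and cells grow — the parameter-recovery tests quantify exactly
this. The clustering metrics show the state assignment recovered the
generator's states perfectly, so the residual error is sampling noise, not
pipeline bias.

The same analysis runs from the shell:

```bash
kerastate simulate --seed 1 --out cohort/
kerastate qc cohort/ --out qc
kerastate run-all --seed 1 --out run/
kerastate print-config        # the fixed analysis defaults
```

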