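# hfqnet

Deterministic mass-action modeling of Hfq-mediated small-RNA signaling.

Bacterial *trans*-acting sRNAs silence (or activate) their target mRNAs by
annealing into sRNA–mRNA duplexes, a reaction catalyzed by the hexameric
RNA chaperone Hfq. In vivo, dozens of sRNAs and target mRNAs compete for a
limited Hfq pool, so the output of any one pair depends on the whole
network: RNAs can be sequestered in singly-bound Hfq complexes or in
*non-cognate* ternary complexes (Hfq bound by an sRNA and an mRNA that
cannot pair). `hfqnet` is a simulator for this competition, built for
modelers and experimentalists who want to ask when duplex formation is
efficient and how robust it is to changes in Hfq availability.

## Model

For `n` sRNA species and `m` target mRNA species the model tracks free Hfq
`H`, free RNAs `S_i`, `T_j`, singly-bound complexes `HS_i`, `HT_j`,
ternary complexes `HS_iT_j` and released duplexes `D_ij` — a system of
`1 + 2n + 2m + 2nm` ODEs. Every species is diluted/degraded at rate β
(default 1 time⁻¹, optionally overridden per species role); Hfq and free
RNAs are produced at rates α. Duplex formation can proceed through two
branches: sRNA binds free Hfq first (association rate k₁, then the mRNA
joins at k₃), or the mRNA binds first (k₂, then the sRNA at k₄);
dissociation constants k₋₁..k₋₄ reverse these steps. Annealing plus duplex
release is a single lumped step with rate k₅(i,j), which also regenerates
free Hfq; duplexes never rebind. The `k5` matrix encodes the pairing
topology: diagonal-only for single-partner networks, dense for
indiscriminate pairing.

Kinetic regimes are summarized by composite parameters: `y1` (relative
mRNA/sRNA affinity), `y2` (association magnitude), `y3` (branch bias),
`y4` (cooperative association), `y5`/`y6` (dissociation magnitude and
cooperativity), `y7` (cognate selection, <1 favors cognate ternary
complexes), `y8` (non-cognate exclusion, >1 disfavors non-cognate ones)
and `y9` (total dissociation including non-cognate routes).

Output metrics follow the same conventions throughout: percent duplex is
`100·D_ij / (T_j + HT_j + ΣHST + ΣD)`, "relative Hfq" is total Hfq over
the focal pair's total mRNA, and sweeping Hfq production yields the
lower/upper bounds (minimum/maximum relative Hfq giving ≥10% duplex) and
the *Hfq robustness*, `log10(upper/lower)`.

## Worked example

Five identical cognate pairs competing for Hfq, with and without
non-cognate exclusion (faster RNA dissociation from non-cognate ternary
complexes, y8 = 10):

```python
from hfqnet import build_scheme, hfq_sweep, bounds_and_robustness, default_alpha_grid

grid = default_alpha_grid(points_per_decade=4)
for regime, kw in [("network_uniform", {}), ("noncognate_exclusion", {"y8": 10.0})]:
    spec = build_scheme(regime, n=5, y9=1.0, k5=1e3, **kw)
    rb = bounds_and_robustness(hfq_sweep(spec, grid))
    print(f"{regime:22s} lower={rb.lower_bound:8.3g} upper={rb.upper_bound:8.3g} "
          f"robustness={rb.robustness:4.2f} max_duplex={rb.max_percent_duplex:5.1f}%")
```

prints

```
network_uniform        lower=   0.649 upper=    33.9 robustness=1.72 max_duplex= 40.5%
noncognate_exclusion   lower=  0.0463 upper=    29.8 robustness=2.81 max_duplex= 84.4%
```

With independent binding the five-pair network converts at most ~40% of
any target mRNA to duplex and tolerates only ~1.7 decades of Hfq
variation; excluding non-cognate ternary complexes more than doubles the
yield and widens the working Hfq range to ~2.8 decades — sequestration in
non-productive complexes is the limiting factor.

Every published-figure study is available as a named scenario
(`fig2`..`fig13`, `s1`) from Python (`hfqnet.Scenario("fig7").run()`) or
the CLI:

```bash
hfqnet scenario fig7 -o out/ --points-per-decade 4   # CSV bundle + summaries
hfqnet sweep config.yaml -o sweep.csv                # custom network
hfqnet robustness sweep.csv                          # bounds from a saved sweep
```

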