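# markovcea

Markov cohort cost-effectiveness analysis for two-arm treatment
comparisons, built around a complete parameterization of bevacizumab +
lomustine (BEV+LOM) versus lomustine monotherapy (LOM) in progressive
glioblastoma, from the perspective of the Chinese healthcare system.

The package is for health economists and methodologists who want a
transparent, scriptable re-implementation of a published three-state
oncology Markov model: every derivation step, accrual convention and
sensitivity-analysis distribution is explicit, testable and overridable
from a plain YAML/JSON configuration.

## The model

Patients occupy one of three health states — progression-free survival
(PFS), progressed disease (PD), death — and move between them once per
monthly cycle over a 10-year horizon. PD is irreversible and death is
absorbing. Monthly transition probabilities come from trial median
survival times under a constant-hazard assumption:

    P(1 month) = 1 − 0.5^(1/m) = 1 − e^(−ln2 / m)

with *m* the median time-to-event in months: PFS→PD from the median PFS,
PFS→death from the median OS, PD→death from the post-progression median
(median OS − median PFS). Stay probabilities are complements.

Costs (USD per cycle per state) and utilities (QALY weight per year,
0.89 in PFS, 0.74 in PD) accrue over the cohort trace, discounted at 5%
per year via the monthly factor (1.05)^(−t/12). The two arms are
compared by incremental cost-effectiveness ratio, ICER = ΔC/ΔE, and net
monetary benefit against a willingness-to-pay threshold of $35,906/QALY
(three times China's 2022 per-capita GDP). Uncertainty is handled by
one-way deterministic sensitivity analysis (tornado) and a 1,000-draw
Monte-Carlo probabilistic sensitivity analysis (Beta draws for
probabilities and utilities, Gamma for costs) summarized as a
cost-effectiveness acceptability curve.

## Worked example

Derive the monthly transition probabilities from the packaged fixture's
medians (4.2/9.1 months for BEV+LOM, 1.5/8.6 for LOM):

```sh
$ markovcea derive --config fixture --out out/
    arm  transition    value  source
BEV+LOM   p_pfs_pfs 0.774523 derived
BEV+LOM    p_pfs_pd 0.152136 derived
BEV+LOM p_pfs_death 0.073341 derived
BEV+LOM     p_pd_pd 0.868091 derived
BEV+LOM  p_pd_death 0.131909 derived
    LOM   p_pfs_pfs 0.552525 derived
    LOM    p_pfs_pd 0.370039 derived
    LOM p_pfs_death 0.077436 derived
    LOM     p_pd_pd 0.906988 derived
    LOM  p_pd_death 0.093012 derived
```

Rounded to two decimals these reproduce all ten published baseline
probabilities. Run the base-case comparison:

```sh
$ markovcea compare --config fixture --out out/
             quantity        BEV+LOM          LOM
        costs_pfs_usd   12369.169391   576.140898
         costs_pd_usd    1111.005552  1924.113713
            qalys_pfs       0.250243     0.090752
             qalys_pd       0.301775     0.522634
      total_costs_usd   13480.174944  2500.254611
          total_qalys       0.552019     0.613386
incremental_costs_usd   10979.920333          NaN
    incremental_qalys      -0.061367          NaN
ce_ratio_usd_per_qaly   24419.783515  4076.151491
    icer_usd_per_qaly -178920.837661          NaN
              nmb_usd    6340.605254 19523.986205
             decision      dominated          NaN
```

The combination costs $10,980 more per patient. Its QALY gain in the
PFS state (+0.16) is outweighed by the monotherapy arm's longer
post-progression sojourn (median 7.1 vs 4.9 months), so incremental
effectiveness is −0.061 QALYs and the combination is *dominated* —
costlier and less effective, hence not cost-effective at $35,906/QALY
(or any threshold). See `docs/methods.md` for why this transition matrix
necessarily produces that sign and how it relates to the trial's
survival medians.

Uncertainty analysis:

```sh
$ markovcea psa --config fixture --n 1000 --seed 7 --out out/ --plot
1000 draws; 100.0% not cost-effective at WTP $35,906/QALY
$ markovcea dsa --config fixture --out out/ --plot
$ markovcea ceac --config fixture --seed 7 --out out/ --plot
```

All commands write diff-able CSV artifacts plus a `run.log` recording
parameters, seed and version. `simulate-trial` generates patient-level
exponential PFS/OS times (2:1 allocation) for end-to-end testing of the
medians → probabilities chain.

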