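# Progressive glioblastoma: bevacizumab + lomustine (intervention) vs
# lomustine monotherapy (comparator).
#
# Clinical inputs are the trial arm medians in months.  Per-cycle costs
# (USD per monthly model cycle) are assembled from published unit prices
# under the package's documented dosing defaults (65 kg body weight,
# 1.72 m2 body surface area; bevacizumab 10 mg/kg q2w, 3 administrations
# per 6-week trial cycle, 100 mg vial at $209.50; lomustine 90 or
# 110 mg/m2 q6w capped at 200 mg, 40 mg capsule at $3.25; 6-week costs
# rescaled to the monthly cycle by 30.4375/42).  PFS per-cycle cost =
# drug acquisition + adverse-reaction management (3.53 / 0.03) + medical
# examination fee (464.67 / 459.04).  PD per-cycle cost = one
# temozolomide unit (67.96) + CT head (141.06) + CBC (2.09) + blood
# biochemistry (15.92) = 227.03 in both arms (second-line treatment
# enters as a configured input).  See markovcea.config.fixture_drug_costs
# for the arithmetic; values here are rounded to the cent.
#
# printed_probabilities holds the published monthly transition
# probabilities with their one-way sensitivity limits.  Note the
# intervention PFS row (0.77 + 0.15 + 0.07) sums to 0.99 as printed; the
# loader warns and the engine renormalizes the stay probability by
# complement when this table is used (precision: fixture).
arms:
  intervention:
    label: BEV+LOM
    median_pfs: 4.2
    median_os: 9.1
    cost_pfs_per_cycle: 3665.95
    cost_pd_per_cycle: 227.03
    cost_death: 0.0
    printed_probabilities:
      p_pfs_pfs: {base: 0.77, low: 0.62, high: 1.00}
      p_pfs_pd: {base: 0.15, low: 0.12, high: 0.18}
      p_pfs_death: {base: 0.07, low: 0.06, high: 0.09}
      p_pd_pd: {base: 0.87, low: 0.69, high: 1.00}
      p_pd_death: {base: 0.13, low: 0.11, high: 0.16}
  comparator:
    label: LOM
    median_pfs: 1.5
    median_os: 8.6
    cost_pfs_per_cycle: 470.85
    cost_pd_per_cycle: 227.03
    cost_death: 0.0
    printed_probabilities:
      p_pfs_pfs: {base: 0.55, low: 0.44, high: 0.66}
      p_pfs_pd: {base: 0.37, low: 0.30, high: 0.44}
      p_pfs_death: {base: 0.08, low: 0.06, high: 0.09}
      p_pd_pd: {base: 0.91, low: 0.73, high: 1.00}
      p_pd_death: {base: 0.09, low: 0.07, high: 0.11}
global:
  utility_pfs: 0.89
  utility_pd: 0.74
  utility_death: 0.0
  discount_rate: 0.05
  horizon_cycles: 120
  wtp: 35906.0
  half_cycle: false
  precision: derived
sensitivity:
  n_iter: 1000
  cost_sd_fraction: 0.25
  wtp_grid: {start: 0.0, stop: 150000.0, step: 1500.0}
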