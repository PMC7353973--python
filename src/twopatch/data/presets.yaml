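# Named parameter presets for the studied scenarios, transcribed from the
# case-study parameterizations. Shared core: a high-quality patch
# (r_H = 2, K_H = 100) and a low-quality patch (r_L = 1, K_L = 50),
# attack rate alpha = 0.05, conversion efficiency c = 0.05, mortality
# mu = 0.1. Variants change only what each scenario varies.

fig1:
  scenario: vary_lambda_p0
  model: {r_H: 2, r_L: 1, K_H: 100, K_L: 50, alpha: 0.05, c: 0.05, mu: 0.1, p: 0, gamma: 1}
  C_T: 15
  levels: {name: beta, values: [1.0]}
  grid: {name: lam, start: 0.01, stop: 20.0, count: 50, spacing: log, include_zero: true}

fig2_solid:
  scenario: vary_lambda_p0
  model: {r_H: 2, r_L: 1, K_H: 100, K_L: 50, alpha: 0.05, c: 0.05, mu: 0.1, p: 0, gamma: 1}
  C_T: 15
  levels: {name: beta, values: [1.0]}
  grid: {name: lam, start: 0.01, stop: 20.0, count: 50, spacing: log, include_zero: true}

fig2_dashed:
  scenario: vary_lambda_p0
  model: {r_H: 2, r_L: 1, K_H: 50, K_L: 50, alpha: 0.05, c: 0.05, mu: 0.1, p: 0, gamma: 1}
  C_T: 15
  levels: {name: beta, values: [1.0]}
  grid: {name: lam, start: 0.01, stop: 20.0, count: 50, spacing: log, include_zero: true}

fig2_dotted:
  scenario: vary_lambda_p0
  model: {r_H: 1, r_L: 1, K_H: 100, K_L: 50, alpha: 0.05, c: 0.05, mu: 0.1, p: 0, gamma: 1}
  C_T: 15
  levels: {name: beta, values: [1.0]}
  grid: {name: lam, start: 0.01, stop: 20.0, count: 50, spacing: log, include_zero: true}

fig3:
  scenario: vary_beta_fixed_lambda_p1
  model: {r_H: 2, r_L: 1, K_H: 100, K_L: 50, alpha: 0.05, c: 0.05, mu: 0.1, p: 1}
  levels: {name: lam, values: [0.1, 10.0, 1000.0]}
  grid: {name: beta, start: 0.0, stop: 10.0, count: 50, spacing: linear}

fig4:
  scenario: vary_lambda_fixed_beta_p1
  model: {r_H: 2, r_L: 1, K_H: 100, K_L: 50, alpha: 0.05, c: 0.05, mu: 0.1, p: 1}
  levels: {name: beta, values: [0.01, 0.1, 1.0]}
  grid: {name: lam, start: 0.01, stop: 20.0, count: 50, spacing: log, include_zero: true}

fig5:
  scenario: covary_p1
  model: {r_H: 2, r_L: 1, K_H: 100, K_L: 50, alpha: 0.05, c: 0.05, mu: 0.1, p: 1}
  levels: {name: gamma, values: [0.1, 1.0, 10.0]}
  grid: {name: beta, start: 0.2, stop: 10.0, count: 50, spacing: linear}
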