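"""Fit the hierarchical model to a small synthetic cohort.

Simulates 6 WKY-like rats for one 65-min extinction session, runs the
adaptive Metropolis-within-Gibbs sampler with a reduced chain, and prints
the group-level posterior table (medians and central 95% credible
intervals, on the conventional reporting scale) next to the generative
medians the data came from.
"""

from dberm import (
    GroupDistribution,
    MCMCConfig,
    WKY_REFERENCE,
    run_mcmc,
    simulate_cohort,
    summarize_posterior,
)

groups = [GroupDistribution("WKY", WKY_REFERENCE, sdlog=0.2)]
cohort = simulate_cohort(groups, n_rats_per_strain=6, n_sessions=1,
                         duration=65.0, seed=5)
print(f"fitting {cohort.n_irts} IRTs from {len(cohort.rat_ids)} rats ...")

chains = run_mcmc(cohort, MCMCConfig(n_samples=2000, burn_in=1000), seed=5)
summary = summarize_posterior(chains)

gen = {
    "L0": WKY_REFERENCE.L0, "w0": WKY_REFERENCE.w0, "b0": WKY_REFERENCE.b0,
    "H_L": 19.37, "H_w": 21.28, "H_b": 4.69,
    "delta_seconds": WKY_REFERENCE.delta_seconds, "omega": WKY_REFERENCE.omega,
}
print(f"\n{'parameter':>14} {'generative':>10} {'median':>9} {'95% CI':>22}")
for _, row in summary.group.iterrows():
    ci = f"[{row.ci_low:8.2f}, {row.ci_high:8.2f}]"
    print(f"{row.parameter:>14} {gen[row.parameter]:>10.2f} "
          f"{row['median']:>9.2f} {ci:>22}")
print("\nEach credible interval should bracket the generative value; the "
      "bout-initiation rate b0 and refractory period delta are the most "
      "sharply identified.")
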