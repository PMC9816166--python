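"""Refit signature exposures on simulated mutations and classify clock
(SBS1/SBS5, aging-like) mutations."""

from lohtime import (
    TumorSimParams,
    count_contexts,
    fit_exposures,
    fixture_catalog,
    is_clock_mutation,
    mutation_posterior,
    simulate_tumor,
)

catalog = fixture_catalog()  # SBS1-like (CpG C>T), SBS5-like (flat), APOBEC-like
sim = simulate_tumor(TumorSimParams(n_mutations=5000), seed=7)

counts = count_contexts(sim.snvs)
fit = fit_exposures(counts, catalog)
print("true exposures     :", sim.truth["exposures"])
print("refitted exposures :", {k: round(v, 3) for k, v in fit.as_dict().items()})
print(f"EM converged in {fit.n_iter} iterations")

n_clock = sum(
    is_clock_mutation(r, mutation_posterior(r, fit, catalog)) for r in sim.snvs
)
print(f"clock mutations (CpG C>T or >50% SBS1+SBS5): {n_clock} / {len(sim.snvs)}")
# Clock mutations accumulate roughly linearly with age, so counting them
# before/after a gain converts molecular time into (approximate) years.
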