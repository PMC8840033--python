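"""Finite-population sample-size arithmetic for a single-centre study."""

import leaktraj as lt

for n_pop in (400, 410, 420):
    n = lt.finite_population_sample_size(
        lt.SampleSizeSpec(population_size=n_pop, margin_of_error=0.05,
                          confidence=0.95, response_fraction=0.5)
    )
    print(f"population {n_pop}/year, 5% margin, 95% confidence -> minimum n = {n}")

print(f"leak prevalence 22/205 = {lt.percentage(22, 205)}%")
print(f"reoperated leaks 17/22 = {lt.percentage(17, 22)}%")

# The finite-population correction caps the usual z^2 p(1-p)/e^2 requirement
# (385 at these settings) by the yearly eligible population.
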