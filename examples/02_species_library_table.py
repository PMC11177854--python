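"""Build a species summary table with bootstrap confidence intervals.

Simulates a cohort at the published per-species sample sizes, extracts the
six FFKPs, and prints the per-species mean, SD and 500-iteration percentile
bootstrap 95% CI for rise time — the same layout as a reference FFKP
library table.
"""

import flashkin as fk

library = fk.default_library()
sizes = [e.n_observed for e in library]
traces, _ = fk.simulate_cohort(
    list(zip(library.species, sizes)), library, fk.AcquisitionConfig(), seed=2
)
records = fk.extract_first_flash(traces)
table = fk.describe_table(records, n_boot=500, seed=2)

rt = table[table.parameter == "RT"]
print("Rise time (ms) per species: mean [95% bootstrap CI], n\n")
for _, row in rt.iterrows():
    print(
        f"  {row.species:26s} {row['mean']:7.1f} "
        f"[{row.ci_lower:6.1f}, {row.ci_upper:6.1f}]  n={row.n}"
    )
print(
    "\nIntervals quantify how precisely each species mean is pinned down at "
    "the field sample sizes; the ctenophore's wide interval reflects its "
    "large intrinsic variability."
)
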