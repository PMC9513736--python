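"""A paired T1/T2 cohort with designed reperfusion, summarized per ring.

Thirty synthetic eyes are imaged twice: T2 reuses each eye's geometry but
lowers the per-ring deficit fraction by ~2-3.6 percentage points (more in the
outer rings) and fragments deficits by a factor of 1.25. Metrics are measured
on the ground-truth masks and compared between visits with the tie-corrected
Friedman test — the expected signature is FD% down, FDa down, FDn up.
"""

from ccrings import directional_cohort_spec, truth_mode_cohort_tables

cohort = directional_cohort_spec(seed=1)
print(f"{cohort.n_eyes} eyes; designed FD% deltas {cohort.fd_percent_delta_per_ring}; "
      f"split factor {cohort.split_factor}")
tables = truth_mode_cohort_tables(cohort)

for name, title in [
    ("fd_percent", "FD% per ring"),
    ("fd_avg_area_um2", "FD average area per ring (um^2)"),
    ("fd_count", "FD number per ring"),
]:
    df = tables[name]
    print(f"\n== {title} ==")
    print(df[["mean_t1", "sd_t1", "mean_t2", "sd_t2", "p_value"]].round(3).to_string())

print("\nFD% and FDa fall at T2 while FDn rises, each with Friedman p < 0.05 —")
print("smaller, more numerous deficits alongside overall reperfusion.")
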