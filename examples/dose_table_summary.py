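"""Summarize the packaged measured skin-dose table.

Loads the per-site OSLD skin doses of the published 20-patient
whole-breast radiotherapy cohort and reproduces its printed
summaries: per-patient means, the cohort minimum, and which site
tends to receive the least / most dose.
"""

from dermachroma import dosimetry

table = dosimetry.reference_dose_table()
print(table.to_string(index=False))

ext = dosimetry.site_extremes(table)
print(f"\ncohort minimum of per-patient mean dose: {dosimetry.cohort_min_mean(table):.1f} cGy")
print(f"inner site is the row minimum in {ext['min_counts']['inner']} of {ext['n_rows']} patients")
print(f"row maximum falls on the upper or lower site in {ext['max_upper_or_lower']} of {ext['n_rows']} patients")
print(
    "\nTangential-field breast irradiation concentrates skin dose on the"
    "\nupper/lower sites and spares the inner site, which these counts show."
)
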