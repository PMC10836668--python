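"""Issue-date prediction with the 80/20 observed/climatology hindcast.

Predictions are issued on 25 February, before the season starts; weather
after the issue date is blended as 0.8 x eventual observation + 0.2 x
training-year mean for that calendar date, emulating a short-range
forecast.  Uses the packaged Islamabad reference coefficient sets.
"""

from pollenseason import BlendConfig, ClimateConfig, make_dataset
from pollenseason import phenology_pipeline as ph
from pollenseason import regression_pipeline as rp

ds, truth = make_dataset(ClimateConfig(seed=1), noise_cv=0.15)
train_years = list(range(2004, 2016))
blend = BlendConfig()  # issue 25 Feb, weights 0.8/0.2

lr_start = rp.load_reference_model("start_5")
lr_peak = rp.load_reference_model("peak_5")
pm_start = ph.load_reference_model("start_5")

print("year  LR start  LR peak  PM start  (reference Islamabad models)")
for year in (2016, 2017, 2018):
    s = lr_start.predict(ds.weather, year, blend=blend, training_years=train_years)
    p = lr_peak.predict(ds.weather, year, blend=blend, training_years=train_years,
                        start_doy=s)
    s_pm = pm_start.predict(ds.weather, year, blend=blend,
                            training_years=train_years)
    print(f"{year}      {s:3d}      {p:3d}       {s_pm:3d}")
print()
print("Values are days-of-year; these coefficient sets were fitted to the")
print("real Islamabad series, so on synthetic weather they show the")
print("prediction mechanics rather than calibrated accuracy.")
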