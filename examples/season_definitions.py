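"""Season start/peak definitions and the MAE metric on a toy series.

The start day is when the running cumulative sum reaches 2.5% or 5% of
the annual total; the peak day is the spring argmax.
"""

import numpy as np
import pandas as pd

from pollenseason import annual_peak_day, annual_start_day, mean_absolute_error

idx = pd.date_range("2005-01-01", "2005-12-31", freq="D")
conc = np.zeros(len(idx))
conc[60:75] = [50, 200, 900, 4000, 9000, 14000, 9000, 5000,
               3000, 2000, 1200, 700, 400, 200, 100]
pollen = pd.DataFrame({"concentration": conc}, index=idx)

start5 = annual_start_day(pollen, 2005, 0.05)
start25 = annual_start_day(pollen, 2005, 0.025)
peak = annual_peak_day(pollen, 2005)
print(f"2.5% start day : {start25}")
print(f"5% start day   : {start5}   (never earlier than the 2.5% day)")
print(f"peak day       : {peak}   (argmax within the Jan-Jun window)")

mae = mean_absolute_error([69, 75, 71], [67, 73, 74])
print(f"example MAE    : {mae:.2f} days  -> mean of |2|, |2|, |3|")
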