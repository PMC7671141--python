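"""Civil twilight tables from on-board solar geometry.

Computes civil dawn/dusk for the study site across the seasons and shows
the polar failure mode: above the arctic circle midsummer has no civil
twilight, which the package reports as a typed error rather than a wrong
time.
"""

from noctograph import FLAGSTAFF, NoTwilightError, Site, civil_twilight
from noctograph.twilight import twilight_table

table = twilight_table(FLAGSTAFF, "2016-06-19", "2016-06-24")
print("civil twilight at the study site (local standard time):")
print(table.frame.to_string())

arctic = Site(latitude=70.0, longitude=0.0, tz_offset_h=0.0)
try:
    civil_twilight(arctic, "2016-06-21")
except NoTwilightError as err:
    print(f"\n70N on the June solstice -> NoTwilightError: {err}")
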