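"""Reference and crop evapotranspiration for one observed summer day.

Builds a typical Mediterranean mid-July observation, computes the FAO-56
reference ET0, then the one-step crop ETc for a mid-season maize canopy,
and reports the implied crop coefficient.
"""

from datetime import date

from etcast import (
    CanopyState,
    SiteMeta,
    WeatherDaily,
    crop_coefficient,
    et0_penman_monteith,
    etc_penman_monteith,
)

site = SiteMeta(site_id="aws16", latitude=40.13, longitude=15.46,
                elevation=413.0)
wx = WeatherDaily(date=date(2014, 7, 15), t_max=30.0, t_min=18.0,
                  rh_mean=60.0, ws10=3.0, rs=289.0)
canopy = CanopyState(date=date(2014, 7, 10), lai=4.5, albedo=0.19)

et0 = et0_penman_monteith(wx, site)
etc = etc_penman_monteith(wx, canopy, site)
kc = crop_coefficient(wx, canopy, site)

print(f"ET0 (grass reference)   : {et0.et:5.2f} mm/day")
print(f"ETc (one-step, maize)   : {etc.et:5.2f} mm/day")
print(f"crop coefficient Kc     : {kc.kc:5.2f}")
print("Kc above 1 means the dense, darker maize canopy transpires more")
print("than the hypothetical well-watered grass under the same weather.")
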