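"""Categorical city attributes used for sampling and stratified reporting."""

# Bailey's ecoregion classification, top ("domain") level only.
ECOREGION_DOMAINS = ("polar", "humid temperate", "dry", "humid tropical")

# WHO regions.
WHO_REGIONS = (
    "Africa",
    "Americas",
    "Eastern Mediterranean",
    "Europe",
    "South-East Asia",
    "Western Pacific",
)

# Gross National Income per capita bands (US$), World Bank style.
GNI_BANDS = ("<1045", "1045-4125", "4125-12746", ">12746")

MIN_CITY_POPULATION = 15_000
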