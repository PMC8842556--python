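# rhcp — regional health care profiles for primary health care

`rhcp` generates **regional health care profiles**: multi-page PDF case
studies describing the population, health status and health-service
structures inside the **car-travel-time catchment area** of any freely
selectable location municipality. Profiles of this kind support the
planning of primary health care units (PHCUs): before establishing a
multi-professional primary-care practice in a municipality, planners need
to know who lives within 10, 15 or 20 minutes by car, how healthy they
are, and which services already exist there.

The package is aimed at health-services researchers and regional health
planners. Because the real inputs of such profiling systems are restricted
administrative data, `rhcp` ships a seeded **synthetic country generator**
at full national scale (2122 municipalities in 116 districts by default)
so the entire pipeline is runnable and testable out of the box.

## The method

For a location municipality *ℓ* and cutoff *T* (minutes), the catchment is
the isochrone membership set on a weighted municipality road graph:

```
C(ℓ, T) = { m : d(ℓ, m) ≤ T }
```

where *d* is the shortest-path car-travel time. Catchments intentionally
cross district borders. Over the catchment, each of **35 indicators in
five domains** (demography/socio-economics, disease prevention and risk
factors, epidemiology and mortality, health care service supply,
outpatient care utilisation) is aggregated by its declared rule:
unweighted mean of municipal values, regional sum, ratio of regional sums
(Σx/Σy × scale), or travel time to the nearest facility.

Each catchment value is then placed in context: the same indicator is
computed for all political districts, the district values are winsorised
at Tukey fences (values outside Q3 + 3·IQR / Q1 − 3·IQR are capped, never
deleted), and the profile reports the district five-number summary
(min, q25, median, q75, max — boxplot whiskers span the total range), the
national value, and the **rank** of the catchment among the districts
(rank 1 = most favourable under the indicator's polarity; ties take the
best rank). An optional comparator district supports head-to-head
comparison. See `docs/methods.md` for the full specification of every
rule.

## Worked example

```python
import rhcp

fx = rhcp.generate_country(seed=1, n_municipalities=300, n_districts=20)
cat = rhcp.load_catalogue("default")
profile = rhcp.build_profile(rhcp.ProfileRequest("M0042", 15.0, "D007"), cat, fx)

print(f"catchment: {len(profile.catchment)} municipalities within 15 min of M0042")
for iid in ["population_catchment", "pct_65_plus", "life_expectancy_men",
            "inhabitants_per_gp", "time_to_hospital", "gp_equivalents_per_100k"]:
    r = profile[iid]; d = r.distribution
    print(f"{iid:28s} catchment={r.catchment_value:10.1f}  district median={d.median:10.1f}  "
          f"national={d.national_value:10.1f}  rank={r.rank}/{d.n_regions + 1}  "
          f"comparator={r.comparator_value:.1f}")

summary = rhcp.render_pdf(profile, cat, fx, "example.pdf")
print(f"wrote {summary.pdf_path} ({summary.page_count} pages) "
      f"and {summary.csv_path} ({summary.table_rows} rows)")
```

prints

```
catchment: 8 municipalities within 15 min of M0042
population_catchment         catchment=   12232.0  district median=   48840.5  national=  938831.0  rank=21/21  comparator=52292.0
pct_65_plus                  catchment=      21.8  district median=      20.0  national=      20.1  rank=2/21  comparator=20.5
life_expectancy_men          catchment=      77.6  district median=      79.8  national=      79.7  rank=21/21  comparator=79.8
inhabitants_per_gp           catchment=    3058.0  district median=    1789.5  national=    1700.8  rank=21/21  comparator=2091.7
time_to_hospital             catchment=      28.0  district median=      14.4  national=      15.2  rank=20/21  comparator=20.2
gp_equivalents_per_100k      catchment=      30.0  district median=      59.7  national=      60.2  rank=21/21  comparator=46.3
```

Reading it: the 15-minute catchment around M0042 holds 12 232 inhabitants
across 8 municipalities — a rural area in this synthetic country. Its
population is older than the district median (21.8 % vs 20.0 % aged 65+,
rank 2 of 21 because many elderly inhabitants signal care needs), general
practitioners are scarce (3 058 inhabitants per GP against a national
1 701; worst rank), the nearest acute-care hospital is 28 minutes away,
and utilised GP capacity is half the national level — a location where a
new primary health care unit would plausibly relieve real pressure. The
PDF contains the map (catchment ochre, location black dot, comparator
district green), the 35-indicator boxplot panel (circle = catchment,
square = comparator, red line = national value), the results table and the
indicator definitions; the sidecar CSV holds the same table at full
precision.

The same is available from the shell:

```bash
rhcp generate-fixture --seed 1 --out fixture/
rhcp profile --fixture fixture/ --location M0042 --cutoff 15 --comparator D007
rhcp batch --fixture fixture/ --out datapoints.csv   # all municipalities x cutoffs x indicators
rhcp validate --fixture fixture/
```

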