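"""Project the male population forward and watch it age.

Builds the census-shaped 2020 male pyramid (ages 40-100) with a Gompertz
life table and projects the closed cohort 30 years: each year every age bin
is thinned by qx and shifted up one age. The printed share of men above 60
rises throughout — the demographic driver of rising prostate-cancer burden.
"""

from prostasim import SyntheticConfig, make_population, project_population

pyramid, life_table = make_population(SyntheticConfig(n_individuals=100_000))
projection = project_population(pyramid, life_table, 30)

print("year  men 40+   mean age   share >60")
for year in (0, 10, 20, 30):
    p = projection[year]
    print(f"{2020 + year}  {p.total:8.0f}   {p.mean_age:7.1f}    {p.fraction_over(60):6.1%}")

print("\nThe cohort shrinks through mortality while its >60 share climbs —")
print("screening-age men make up an ever larger part of the population.")
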