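"""Simulate a search-encounter survey and look at what it produced.

A survey consists of GPS search tracks (correlated random walks inside the
searched rectangle), a habitat-suitability mask over the buffered state
space, a true population of activity centres, and the sightings that the
cloglog encounter model generated along the searched pixels.

Run:  python examples/01_simulate_survey.py
"""

import numpy as np

from searchscr import ScenarioConfig, mmdm, simulate_survey

# the default scenario: 20 x 20 km searched area, 8 km buffer, 40 animals,
# 30 daily occasions, sigma_m twice sigma_f
scenario = ScenarioConfig()
survey = simulate_survey(scenario, seed=7)

space, effort, truth = survey.space, survey.effort, survey.truth

print(f"state space : {space.nx} x {space.ny} pixels of "
      f"{space.side:.2f} km ({space.total_area:.0f} km^2, "
      f"{space.percent_unsuitable:.1f}% unsuitable)")
print(f"search effort: {effort.total_km:.0f} km over "
      f"{effort.n_occasions} occasions, "
      f"{int(effort.active.any(axis=1).sum())} of {effort.n_traps} "
      f"trap pixels visited")

n_det = int(truth["detected"].sum())
print(f"population  : {len(truth)} animals "
      f"({int(truth['sex'].sum())} male), {n_det} detected, "
      f"{len(survey.sightings)} sightings")
print(f"true density: {survey.true_density:.2f} / 100 km^2 of suitable habitat")

# the movement summary used to justify the buffer width
by_sex, _ = mmdm(survey.sightings, group="sex")
print(f"MMDM        : females {by_sex['F']:.2f} km, males {by_sex['M']:.2f} km")

# per-individual detection counts
if survey.enc is not None:
    tot = survey.enc.individual_totals
    print(f"detections  : {tot.sum()} cells, per-individual "
          f"min/median/max = {tot.min()}/{int(np.median(tot))}/{tot.max()}")
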