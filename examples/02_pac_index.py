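"""Mueller's potential apparent competition index on a daily network.

Starts from the 2x2 matrix that can be checked by hand, then computes the
per-species interspecific (column mean off the diagonal) and intraspecific
(diagonal) indices for one synthetic sampling day.
"""

from datetime import date

from beepac import data_model as dm, network_builder as nb
from beepac.network_builder import DailyNetwork
from beepac.pac import interspecific_index, intraspecific_index, pac_matrix
from beepac.synthetic import SyntheticConfig, generate_community

net = DailyNetwork(date(2020, 7, 15), 2020, ["B1", "B2"], ["P1", "P2"], [[2, 0], [1, 1]])
pac = pac_matrix(net)
print("hand-checkable 2x2 example, d (rows = target, cols = acting):")
print(pac.to_frame().round(4).to_string())
# d_21 = 1/3: B1 takes 2/3 of P1's visits, and P1 is half of B2's diet.

visits, *_ = generate_community(SyntheticConfig(seed=1))
visits = dm.filter_rare_species(dm.restrict_to_core_season(visits), 20)
day = nb.build_daily_networks(visits)[0]
pac = pac_matrix(day)
print(f"\n{day.date}: {len(day.bee_labels)} bee x {len(day.plant_labels)} plant network")
print("interspecific index (mean effect of each acting species on the rest):")
for sp, v in interspecific_index(pac).items():
    print(f"  {sp}: {v:.3f}")
print("intraspecific index (each species' dominance of its own plants):")
for sp, v in intraspecific_index(pac).items():
    print(f"  {sp}: {v:.3f}")
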