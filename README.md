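# ecodecnet

Eco-decisional well-being networks: a toolkit for communities that want to
treat their decisions as an integrated system rather than a list of
independent choices.

Community actions (build greenspace, support urban revitalization, dredge a
river) change ecosystem, social, and economic services; changes in services
move the domains of human well-being; the domains combine into a composite
Human Well-Being Index (HWBI).  `ecodecnet` models this chain as a layered
weighted directed network — 29 action categories (AC), 22 services (S),
8 well-being domains (D), and one HWBI node — where each link carries a
normalized influence weight in [0, 1] derived from stakeholder engagement.
Network theory then provides both pathway-level decision support (which
action, through which service, moves which domain the most?) and whole-system
indices of how organized the decision space is.

## The indices

With link weights `T_ij`, total system throughput `TST = Σ T_ij`, and joint
flow probabilities `p_ij = T_ij / TST` (logs base 2):

| quantity | definition | meaning |
|---|---|---|
| `H` | `−Σ p_ij log2 p_ij` | flow entropy (bits) |
| `AMI` | `Σ p_ij log2(p_ij / (p_i· p_·j))` | how much a flow's source says about its destination |
| `A` | `TST × AMI` | ascendancy: the scaled mutual constraint of the network |
| `Cap`, `Φ` | `TST × H`, `Cap − A` | capacity (upper bound on A) and overhead (flexibility) |
| `C` | `2·TST / n` | mean connectivity: weighted links per node |
| `R` | `2^AMI` | realized roles: effective number of distinct influence pathways |
| `c_eff` | `2^(H/2)` | entropy-based effective link density |

Real ecological flow networks cluster in a "window of vitality"
(connectivity ≈ 1–3.01, roles ≈ 2–4.5), approximated here as an inclusive
rectangle for comparison plots.

The package also provides: random-network ensembles at three constraint
levels (fully random digraphs, all 822 permissible layered links, a fixed
community link set) with power-law and ascendancy-peak summaries; the
community weight pipeline (normalize raw scores within each link type and
data source, optionally standardize service→domain scores by national
regression factors, consolidate across sources, assemble); exhaustive
decision-pathway enumeration and ranking; and action-by-domain trade-off
tables.

## Worked example

Build a synthetic community network (287 links over the 60-node taxonomy,
mean link weight ≈ 0.70, emulating consolidated workshop scores) and inspect
it:

```python
from ecodecnet import generate_synthetic_community, index_report, rank_paths

raw_scores, net = generate_synthetic_community(seed=1)
print(index_report(net).to_json())
for i, p in enumerate(rank_paths(net, "AC01", k=3), 1):
    print(i, " -> ".join(p.nodes), round(p.weight, 4))
```

prints

```
{
  "tst": 210.75381134858625,
  "h": 8.133577541166204,
  "ami": 2.4123285304135402,
  "ascendancy": 508.4074320095876,
  "capacity": 1714.1824667000403,
  "overhead": 1205.7750346904527,
  "mean_connectivity": 7.0251270449528755,
  "realized_roles": 5.323328254245742,
  "effective_link_density": 16.758124245469585,
  "n": 60,
  "links": 287
}
1 AC01 -> S09 -> D7 -> HWBI 0.7077
2 AC01 -> S13 -> D2 -> HWBI 0.7014
3 AC01 -> S17 -> D6 -> HWBI 0.6869
```

The network carries about 211 units of influence over 287 links, averaging
7.0 weighted links per node, and supports about 5.3 effective influence
roles — the system behaves as if roughly five distinct pathway bundles link
actions to well-being.  Ascendancy (508) sits well below capacity (1714):
most of the decision space is redundancy/flexibility rather than committed
structure.  The ranked rows show the three most influential routes from
action category AC01 to the index, with their product-aggregated path
weights.

The same workflows are scriptable from the shell:

```sh
ecodecnet fixtures community --seed 1 --out-dir fx/
ecodecnet indices fx/network.json
ecodecnet paths --network fx/network.json --action AC01 --top 3
ecodecnet simulate size-sweep --sizes 20,40,60,80,100 --reps 100 --seed 42 \
    -o sweep.csv --plot-dir figs/
```

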