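# flysoc

Constant-count tracking of walking *Drosophila* groups and directed
social-interaction network analysis.

Groups of flies walking in a closed 2-D arena are recorded as bright
~20-pixel bodies on a dark background. Quantifying their social
structure requires three hard steps: (1) keeping every fly's identity
through occlusions, (2) detecting brief head-to-tail touch interactions
from trajectories alone, and (3) comparing networks across experimental
repeats whose nodes have no natural correspondence. `flysoc` implements
the full pipeline plus a synthetic arena simulator with frame-exact
ground truth, so every stage is testable without any recorded video.

## The methods at the core

**Constant-count tracking.** The number of flies N in a closed arena is
constant, so the tracker emits exactly N states per frame. Frames are
background-subtracted and segmented into 8-connected components; when
fewer than N blobs appear, the missing flies are inside merged blobs. A
bipartite graph links the N flies of frame t−1 to the blobs of frame t,
with candidate merged blobs (area > 1.5× the typical single-fly area)
duplicated until the right side also has N nodes. The minimum-cost
perfect matching (Hungarian algorithm on Euclidean distances) decides
how many flies each blob holds; merged blobs are split into that many
Gaussian-mixture components by EM over their pixels, and a second
Hungarian matching hands each split center its identity. Heads and
tails are the principal-axis endpoints, the head chosen along the
smoothed direction of motion.

**Touch interactions.** A touch is a single-frame head-to-tail contact
of an ordered pair (interactor → interacted). Each candidate
(pair, frame) is described by 22 temporal features — the 11 head-to-tail
distances over the 11-frame window centered on the frame, and the 11
magnitudes of the interactor's displacement from its window-center
position relative to the interacted fly — and classified by an
RBF-kernel SVM trained on labelled touch/no-touch frames. Touch frames
become a *touch interaction* when they last ≥ 15 consecutive frames
(~0.5 s at 30 fps); gaps < 15 frames are bridged first, and distinct
interactions require a ≥ 15-frame separation.

**Social networks.** Interactions are tallied into an N×N adjacency
matrix (row = interactor, zero diagonal), max-normalized, and
quantified by nine parameters: in/out/total degree and their weighted
versions, Fagiolo's weighted-directed clustering coefficient,
betweenness centrality (edge length 1/weight), assortativity, global
efficiency, transitivity, density, and weighted total interaction.

**Average networks.** Networks from different repeats are aligned by
the permutation P minimizing ‖W₁ − P W₂ Pᵀ‖_F (graduated assignment —
an annealed softassign/Sinkhorn relaxation with discretization and
local refinement), then combined by the incremental running mean
M ← ((i−1)/i)·M + (1/i)·W_i°. Group comparisons use the Mann-Whitney U
test and the Scheirer–Ray–Hare rank-based two-way analysis.

## Worked example

The six-fly sample network in which fly X1 touches X2…X6 and receives
touches from X2, X3 and X5:

```python
from flysoc import TouchInteraction, build_adjacency, network_parameters

events  = [TouchInteraction(1, j, 0, 20) for j in (2, 3, 4, 5, 6)]
events += [TouchInteraction(i, 1, 200 * i, 200 * i + 20) for i in (2, 3, 5)]
net = build_adjacency(events, 6)
per_node, global_params = network_parameters(net)
print(per_node.to_string(index=False))
```

```
 fly_id  in_degree  out_degree  degree  weighted_in_degree  weighted_out_degree  weighted_degree  clustering_coefficient  betweenness_centrality
      1          3           5       8                 3.0                  5.0              8.0                     0.0                     0.6
      2          1           1       2                 1.0                  1.0              2.0                     0.0                     0.0
      3          1           1       2                 1.0                  1.0              2.0                     0.0                     0.0
      4          1           0       1                 1.0                  0.0              1.0                     0.0                     0.0
      5          1           1       2                 1.0                  1.0              2.0                     0.0                     0.0
      6          1           0       1                 1.0                  0.0              1.0                     0.0                     0.0
```

Fly X1 leaves edges to five flies (out-degree 5) and receives edges
from three (in-degree 3); its degree is the sum, 8. Every edge carries
one interaction, so the normalized weighted degrees coincide with the
binary ones. X1 sits on most indirect shortest paths (betweenness 0.6),
and no triangles close around any node (clustering 0). The global
parameters print as

```
assortativity: -0.9923          # hub connects to low-degree flies
global_efficiency: 0.4667
transitivity: 0.0000
density: 0.2667                 # 8 of 30 possible directed edges
weighted_total_interaction: 8.0000
```

## Command line

Each pipeline stage is a subcommand (`flysoc --help`):

```bash
flysoc simulate --n-flies 16 --frames 1800 --touches 30 --seed 7 --out sim/
flysoc track    --video sim/video.tif --n-flies 16 --out tracks.csv
flysoc train-touch --tracks sim/truth_tracks.csv --labels sim/truth_labels.csv --out touch.model
flysoc classify --tracks tracks.csv --model touch.model --out events.csv
flysoc network  --events events.csv --n-flies 16 --out net/
flysoc average  --nets net/adjacency.csv net2/adjacency.csv --out avg.csv
flysoc compare  --params-a ctrl.csv --params-b iso.csv --out stats.csv
```

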