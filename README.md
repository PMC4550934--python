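# ppi-richclub

Network analysis of disease protein–protein interaction (PPI) networks:
rich-club detection against a degree-preserving random null, small-world and
scale-free characterization, Markov-clustering (MCL) module decomposition,
and Fisher-exact drug-target enrichment. Built for the style of study in
which a curated disease interactome (e.g. proteins deregulated after brain
ischemia, wired by STRING interactions with combined score ≥ 0.4) is mined
for a densely interconnected hub core — a *rich club* — whose members are
candidate drivers and drug targets.

## The statistics at the core

For a simple undirected graph, the **rich-club coefficient** at degree
threshold *k* is

    φ(k) = 2·E_>k / (N_>k · (N_>k − 1))

where N_>k counts nodes of degree > k and E_>k the edges among them. φ rises
with k even in random graphs, so significance is judged by the **normalized
coefficient**

    ρ(k) = φ(k) / ⟨φ_random(k)⟩

with the average taken over degree-preserving randomizations (double edge
swaps that keep every node's degree and reject loops and duplicate edges).
ρ(k) > 1 marks a club the degree sequence alone cannot explain; the club
core is read from the contiguous ρ > 1.3 region. Supporting measures:

- **small-world coefficient** σ = (C/C_rand)/(L/L_rand) against
  Erdős–Rényi graphs matched on |V| and |E|;
- power-law degree exponent γ by continuous MLE with KS-minimized k_min;
- **MCL** modules (expansion/inflation flow simulation, implemented from
  the algorithm definition) with a module meta-network;
- two-sided **Fisher exact** enrichment (minimum-likelihood rule, computed
  from the hypergeometric mass) of drug-target sets in the network and in
  its rich club, with Benjamini–Hochberg FDR.

Because curated interactomes are rarely redistributable, the package ships a
synthetic generator that emulates one — scale-free topology, a planted
rich-club core, block modules, hub-elevated literature frequencies,
hub-biased drugs — with machine-readable ground truth, so every stage is
validated by recovery of what was planted.

## Worked example

The `analysis/` scripts run the full study on a synthetic 886-protein
interactome (~17,400 interactions, 30-hub planted core):

```bash
python analysis/01_generate_network.py --seed 0
python analysis/02_network_topology.py --seed 0
python analysis/03_rich_club.py --seed 0
python analysis/04_modules.py
python analysis/05_drug_enrichment.py
```

which prints (seed 0):

```
degree exponent gamma = 2.82 (MLE, k_min=23) -> scale-free regime
clustering C = 0.1042 vs random 0.0444; path length L = 2.136 vs random 2.123
small-world sigma = 2.33 (small-world organization)
significant rich club over degrees 39-196, peak rho = 1.56 at k = 114
core (rho > 1.3 rule): 51 proteins; strongest component (phi plateau): 5; overlap 5
core proteins are 3.7x more frequently reported (Welch p = 1.8e-25)
...
  drug_biased_2: hits 41/51 of club (80%), OR = 39.24, p = 1.34e-29
  drug_uniform_1: hits 3/51 of club (6%), OR = 0.38, p = 0.137
```

Reading: the degree distribution is scale-free (γ ≈ 2.8); clustering is
2.3× the random expectation at random-graph path lengths (σ > 1,
small-world); a rich club spans degrees ≈ 39–196 whose 51-protein core
contains the 30 planted hubs; core proteins carry ~4× the literature
frequency (the planted effect); and the generator's hub-biased drugs — the
planted analogue of a pleiotropic therapeutic — hit 70–80 % of the club with
Fisher p < 10⁻²², while uniform drugs do not. The same pipeline runs on real
data from a STRING-style edge list:

```bash
ppi-richclub run-all --edges my_network.tsv --annotations ann.tsv \
    --drug-targets drugs.tsv --seed 1 --out results/
```

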