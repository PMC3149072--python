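# protrp

Discovery, clustering, and classification of **proline-rich tandem-repeat
proteins (TRPs)** targeted to plant secretomes.

Plant cell walls contain secreted structural glycoproteins — extensins,
proline-rich proteins, arabinogalactan proteins — built from short tandem
repeats such as the extensin Ser-Pro₄ motif. Their biased, low-complexity
composition defeats BLAST- and HMM-style homology search, so mining them
from large EST/protein corpora needs methods built for repeats. `protrp`
implements that pipeline end to end for bioinformaticians studying wall
proteins and repeat evolution:

1. **TR detection** — a seed-and-extend detector under the standard
   parameter contract (minimum copy number *minC* = 2, per-copy character
   identity *i* = 0.7, aggregate consensus match *I* = 0.8, max
   consecutive gaps *g* = 3, minimum domain length *minD* = 12). A TR
   domain is a window read as consecutive copies of a period-*p*
   consensus; detection is exact against a brute-force window search on
   small instances.
2. **Filter cascade** — Pro-rich consensi (≥ 20 % Pro), *TR Modules*
   (≥ 100 aa, or ≥ 50 aa and ≥ 1/3 of the protein), secretion gating on
   external signal-peptide predictions (HMM probability ≥ 0.7 or all five
   NN components "Yes"), GPI-anchor calls (specificity ≥ 99.5), and
   clusterability (period > 3, no `X`/stop).
3. **Cyclic-permutation-aware clustering** — each TR domain becomes a
   400-entry dipeptide compositional vector (ordered adjacent residue
   pairs, normalized by domain length; for `PVPVKPVPVK`: PV = 4, VP = 2,
   VK = 2, KP = 1, then ÷ 10). An ensemble engine partitions the vectors
   and reports per-pair co-clustering confidence; each cluster is then
   quality-controlled at the sequence level: members are rotated into a
   maximal-agreement cyclic frame (PVYK = VYKP = YKPV = KPVY), a
   column-majority master consensus is built, and the cluster is accepted
   when the mean mismatch fraction against the master (*consensus error*)
   meets the homology threshold *E* = 0.4, with failing clusters
   recursively re-clustered to the stricter *E* = 0.3 or the minimum
   size of 10.
4. **Fuzzy cluster network** — prolines are stripped, members of each
   cluster are averaged into one vector, and clusters are linked by
   ensemble co-clustering confidence over Pearson-correlation distances;
   edges below confidence 0.04 are removed and isolated nodes dropped.
   Exports GraphML/SIF plus node attributes (member/species/protein
   counts, prominence tier, taxonomy retention rate).
5. **Regex TR taxonomy** — class definitions in a compact mini-syntax
   (`[TS]P{3,4}[VA]{1,2}[TS].P and not [HY]`) matched phase-insensitively
   against consensus motifs, plus periodicity classes *n* / *n*+1 /
   *n*−1 relative to multiples of 3 (the symmetry of the polyproline-II
   helix) and proline backbone categories (SPₙ, TPₙ, interspersed P₁,
   regular P₂ blocks, …).

A synthetic-data module plants TR protein families with configurable
motifs, copy numbers, substitution rates, signal-peptide-like leaders and
EST-like nucleotide encodings, so every stage is testable without any
download.

## Worked example

```python
from protrp import detect_repeats, dipeptide_vector, autosome_tr_cluster
from protrp.autosome_tr import dipeptide_index, EngineParams

d = detect_repeats("MKVILSPPPPYVYKSPPPPYVYKSPPPPYVYKSPPPPYVYKAQDE")[0]
print((d.start, d.end), d.period, d.consensus, round(d.proline_fraction, 2))
# (2, 42) 9 VYKSPPPPY 0.44

v = dipeptide_vector("PVPVKPVPVK")
print(v[dipeptide_index("PV")], v[dipeptide_index("VP")])
# 0.4 0.2

motifs = ["SPPPPYVYK", "SPPPPYVHK", "SPPPPAVYK",
          "PELPKPVP", "PELPKPAP", "PELPKPVA"]
clusters, singletons = autosome_tr_cluster(motifs, engine=EngineParams(seed=0))
for c in clusters:
    print(c.members, c.master_consensus, round(c.consensus_error, 3))
# ['SPPPPYVYK', 'SPPPPYVHK', 'SPPPPAVYK'] SPPPPYVYK 0.074
# ['PELPKPVP', 'PELPKPAP', 'PELPKPVA'] PELPKPVP 0.083
```

The detector reports the repeat region `[2, 42)` with period 9 and a
consensus stored in an arbitrary cyclic phase (`VYKSPPPPY` ≡
`SPPPPYVYK`); the clustering groups the two motif families regardless of
phase and reports each family's master consensus with its consensus
error (mean mismatch of members against the master).

A CLI mirrors the library (`protrp simulate | translate | detect |
filter | cluster | network | classify | periodicity | run`); `protrp run`
executes the whole pipeline from a YAML config and writes per-stage
TSVs, network exports, and a manifest with the seed and a configuration
hash so identical configs reproduce identical bytes.

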