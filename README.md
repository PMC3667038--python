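# disorderscape

Intrinsic structural disorder profiling for protein cohorts, built around
the analysis style used for the human ubiquitination system (E1 → E2 → E3
enzymes). Single-subunit E3 ubiquitin ligases bind the ubiquitin-charged E2
and the substrate on one polypeptide chain; the question the pipeline
answers is *where the disorder lives*: in the chain overall, inside or
outside the E2-binding domain (RING / U-box / HECT), in the inter-domain
linkers that let substrate and E2 diffuse toward each other, and as a
function of a protein's position in the interaction network.

The package is for structural bioinformaticians who have per-residue
disorder predictor output (IUPred-style scores, FoldIndex-style
unfoldability indices, or the built-in charge–hydropathy baseline) plus
UniProt-style domain annotations and STRING-style interaction edges, and
want reproducible family-level disorder statistics.

## What it computes

For a residue score track *s₁…s_L* with threshold *t* (disordered iff
*sᵢ ≥ t* for high-is-disordered tracks, *sᵢ < t* for unfoldability
indices):

* **Disorder content** = 100 · (#disordered residues) / *L*; proteins with
  content ≥ 50% are "mostly disordered" (class D).
* **Long disordered regions (LDRs)**: maximal chains of disordered runs in
  which intervening ordered gaps of ≤ 3 residues are ignored, containing
  ≥ 30 disordered residues. Chaining is transitive; the longest-run metric
  deliberately uses raw runs without gap merging.
* **Domain-partitioned disorder**: each chain is split into E2-binding
  domains, transmembrane segments (discarded), and the remainder; the
  family summary averages per-protein region percentages without weighting
  and tests the remainder excess with a one-tailed Mann-Whitney U test.
* **Linkers**: un-annotated intervals between an E2-binding domain and an
  adjacent substrate-recognition domain, uninterrupted by any other domain
  or transmembrane segment, summarized by length bins
  ([1,50], (50,200], (200,∞)) and mean raw disorder score.
* **Connectivity classes**: degree *k* = number of distinct interaction
  partners after merging edge sources; hubs (*k* ≥ 25), intermediately
  connected proteins (4 ≤ *k* ≤ 24), non-hubs (*k* ≤ 3), with a
  hub-vs-non-hub disorder comparison.
* **Redundancy filtering**: greedy CD-HIT-style clustering at 85% identity
  (Needleman–Wunsch matches / shorter length), keeping the best-annotated
  representative.

The Mann-Whitney U test is self-implemented: exact enumeration of all
C(n₁+n₂, n₁) labelings for max(n₁, n₂) ≤ 8, otherwise a tie-corrected,
continuity-corrected normal approximation.

A seeded synthetic-cohort generator (block architectures: disordered tails
and linkers, ordered E2-binding and substrate-recognition domains, with
autocorrelated score noise and heavy-tailed or exactly pinned network
degrees) makes every stage testable without any database downloads.

## Worked example

Generate a 20-protein synthetic cohort and run the full pipeline:

```bash
disorderscape simulate --seed 11 --out-dir demo/sim
cat > demo/run.yaml <<EOF
fasta: demo/sim/cohort.fasta
scores: demo/sim/scores.tsv
orientation: high_is_disordered
domains: demo/sim/domains.tsv
edges: [demo/sim/edges.tsv]
out_dir: demo/out
EOF
disorderscape run --config demo/run.yaml
```

`demo/out/family_summary.tsv` (overall disorder per family):

```
#family	n_proteins	mean_length	mean_disorder_content	mean_n_disordered	n_mostly_disordered	n_with_ldr
U-box	4	472.50	19.87	94.00	0	4
HECT	4	494.25	20.00	99.00	0	4
sRF	12	438.17	19.83	87.08	0	10
```

The generator was asked for 20% whole-protein disorder, and each family's
mean disorder content lands at ~20%; most proteins carry at least one LDR.

`demo/out/region_summary.tsv` (domain-partitioned disorder):

```
#family	n_proteins	avg_e2_disorder	avg_remainder_disorder	p_value
U-box	4	0.00	22.38	0.01
HECT	4	1.88	22.43	0.01
sRF	12	1.11	22.83	1.46e-05
Total	20	1.04	22.66	2.24e-08
```

E2-binding domains are nearly fully ordered (~1% disorder) while the
remainder carries ~23%: the disorder is concentrated outside the
E2-binding domain, and the one-tailed Mann-Whitney p-values quantify that
excess per family.

Subcommands `cluster`, `score`, `segment`, `partition`, `linkers` and
`network` expose the individual stages; the same functionality is available
as a library (`import disorderscape`).

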