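# germscan

Discovery of high-copy **germline-restricted satellite repeats** from
comparative two-tissue shotgun sequencing.

Some animals discard parts of their genome from somatic cells during early
development (programmed DNA elimination / chromatin diminution), while the
germline retains the full complement. The eliminated chromatin is typically
packed with tandem satellite repeats — short (13–57 bp) core units repeated
head-to-tail over tens of kilobases to megabases, disrupted by small indels
and duplicated as inverted cassettes. `germscan` finds such families from
nothing but raw reads of a germline tissue (e.g. sperm) and a somatic
tissue (e.g. blood):

1. **k-mer spectrum** — count canonical 31-mers per tissue; keep k-mers with
   count ≥ 3× the modal copy number of each spectrum;
2. **assembly** — compress the abundant k-mers on a de Bruijn graph
   (node size 29, relative coverage cutoff); tandem units appear as cycles;
3. **library merge** — optionally replace de novo sequences matching a
   reference repeat library (>90% identity over >80% of length) and exclude
   sequences matching a known repeat at ≥99% identity;
4. **comparative coverage** — place both read sets on the library, scan
   intervals (v=5000, l=0, a=b=10, caps 12M), score each interval as
   `log2(standardized germline coverage / standardized somatic coverage)`
   and estimate its genomic span as `length × (depth / modal depth)`;
5. **germline filter** — keep score > 5 and span > 40 kb (both strict);
6. **clustering** — greedy identity clustering (c=0.8, aS=aL=0.3) with
   cross-alignment merging (≥4 hits), yielding repeat families;
7. **annotation** — tandem core unit, inverted cassettes, best scaffold,
   and a somatic-coverage ranking that nominates centromeric candidates.

A synthetic-data module generates germline/somatic genome pairs with
planted shared and germline-restricted families plus a ground-truth table,
so the whole pipeline is testable end-to-end without external data.

## Worked example

Simulate the packaged standard scenario (two 2 Mb genomes, three shared
pericentromeric families, six germline-restricted families with 13–57 bp
units and ~66 kb planted spans, 40× reads) and run the full pipeline:

```python
from germscan.pipeline import run_standard_scenario, evaluate_recovery
from germscan.synth import STANDARD_COVERAGE

result, truth, paths = run_standard_scenario("work", seed=42)
print(result.candidates[["sequence_id", "enrichment_score", "estimated_span"]])
report = evaluate_recovery(result, truth, STANDARD_COVERAGE)
print(f"recall={report.recall} precision={report.precision} "
      f"score_mae={report.score_mae:.3f}")
```

Output (seed 42):

```
  sequence_id  enrichment_score  estimated_span
0    rep00001         15.515518    68461.538462
1    rep00003         15.781719    67889.743590
2    rep00005         16.090232    67976.923077
3    rep00006         16.417435    67328.205128
4    rep00008         16.930579    67261.538462
5    rep00010         17.649049    68512.820513
recall=1.0 precision=1.0 score_mae=0.009
```

Six candidate sequences pass the germline filter — one per planted
restricted family, none from the shared families. Each candidate's
enrichment score is the log2 ratio of modal-standardized germline vs
somatic coverage (a family absent from the soma is scored against a
1-read-depth floor, hence values around 15–18 = log2(copies × coverage)),
and its estimated span reconstructs the planted ~66 kb array extent to
within a few percent. `result.cluster_table` shows the six singleton
clusters (one family each) and `result.annotations` reports each family's
detected core unit length (13/21/30/38/47/57 bp), periodicity score and
best scaffold.

The same stages are scriptable from the shell:

```bash
germscan simulate -o scenario --seed 42
germscan kmers -r scenario/germline_reads.fq -k 31 --multiplier 3 -o sperm_kmers.tsv
germscan assemble --kmers sperm_kmers.tsv --node-k 29 -o library.fa
germscan run-all --config pipeline.yaml
```

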