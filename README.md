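# tcskit

Comparative genomics of bacterial two-component signalling (TCS) gene sets.
Given per-genome annotation bundles (protein FASTA plus gene-order and
domain tables), `tcskit`:

* classifies TCS proteins (histidine kinases, hybrid kinases, response
  regulators, phosphotransfer proteins) and computes R/T/H architecture
  strings and domain-composition matrices;
* groups TCS genes into genomic **foci** and categorises their organisation
  (orphan / paired / complex, with "intricate" foci flagged) plus per-genome
  and cohort summary statistics;
* clusters TCS proteins across genomes into orthologue/paralogue groups
  with a two-tier similarity scheme (0.90 / 0.30), reciprocal-best-hit
  validation and difference flags (size, architecture, family,
  organisation, multiplicity);
* builds 16S p-distance matrices, neighbour-joining trees with bootstrap
  support, distance-band discretisation, and fits the orthology-vs-distance
  exponential decay;
* infers evolutionary events between genomes (singletons, duplications,
  organisation / architecture / family / size changes, pseudogenisation,
  HGT candidates via a labelled reference set, relocations from synteny
  dot-plots) and summarises their frequencies;
* ships a genome **simulator** that evolves annotated genomes along a tree
  with planted events and an exact truth log, so the entire pipeline is
  testable without external data.

## Command line

All functionality is exposed through the `tcs` command:

```bash
# simulate two sister genomes with planted events
tcs simulate --seed 7 --out sim/           # + optional --config sim.yaml

# per-genome stages
tcs classify --bundle sim/A --out tcs_proteins.tsv
tcs foci     --bundle sim/A --out foci.tsv
tcs stats    --bundles sim/A --bundles sim/B --out table.tsv

# comparative stages
tcs cluster  --bundles sim/A --bundles sim/B --high 0.90 --low 0.30 --out clusters.tsv
tcs events   --bundles sim/A sim/B --clusters clusters.tsv \
             --reference sim/reference.faa --out-dir events/
tcs distance --aln ssu.aln.fna --bootstrap 1000 --seed 7 --out-tree tree.nwk

# everything at once
tcs run --config pipeline.yaml
```

`pipeline.yaml` maps directly onto `tcskit.report.PipelineConfig`:

```yaml
bundle_dirs: [sim/A, sim/B]
out_dir: report/
reference: sim/reference.faa
seed: 7
```

### Bundle format

A bundle directory contains `proteins.faa` (FASTA), `genes.tsv`
(locus_tag, contig, rank, strand, start, end, pseudogene, protein_id),
`domains.tsv` (protein_id, kind, subtype, start, end with kinds in
{receiver, transmitter, phosphoacceptor, input, output, TM}), an optional
`ssu.fna` 16S sequence and an optional `meta.json` (genome id +
completeness flag). Tables are tab-separated with `.` for absent values;
gene coordinates are 1-based nucleotide, domain coordinates 1-based
residue, and `rank` is the 0-based gene-order index.

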