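# zwmarker

In-silico evaluation of PCR sexing markers on avian ZW genomes.

Most birds cannot be sexed by looking at them. The standard molecular
workaround exploits the ZW sex-chromosome system (females ZW, males ZZ):
conserved genes such as *CHD1*, *NIPBL* and *SPIN* have diverged copies
(gametologs) on Z and W, and when the Z and W copies of an intron differ in
length by ΔL, a primer pair in the flanking exons yields two PCR products in
females and one in males. Whether a given marker actually works for a given
species depends on three things that can be checked computationally before
anyone touches a thermocycler: does the primer pair amplify where its name
says it does, does a second (W or translocated) copy exist and how long is
it, and can a standard agarose gel separate the two bands?

`zwmarker` implements that whole desk workflow as a tested pipeline:

1. **`sequence_io`** — FASTA/TSV/YAML I/O, IUPAC alphabet utilities; roles
   (Z/W/scaffold) come from a side-car YAML map, never from headers.
2. **`gene_structure`** — exon/intron inference by spliced mRNA-to-genome
   mapping (MEM seeding + co-linear chaining, GT..AG-aware boundaries),
   GFF3/TSV export.
3. **`insilico_pcr`** — degenerate-primer binding sites (IUPAC matching,
   mismatch budget, exact 3' window), product enumeration, and per-product
   exon/intron composition such as `E22(30 bp)/I22(185 bp)/E23(152 bp)`.
4. **`homology_search`** — seed-and-extend local alignment (exact affine
   Smith–Waterman on candidate windows, numba-compiled) with co-linear HSP
   chaining, so a copy with a multi-kilobase intron indel is still measured
   end-to-end; BLAST-outfmt-6-style export.
5. **`copy_comparison`** — pairing the Z amplicon with its best non-Z copy,
   ΔL with direction, partial-copy flagging.
6. **`gel_model`** — band migration d = t·V·exp(α(g) − β(g)·ln L) with a
   frozen per-percentage calibration; separated / indistinct / comigrating
   band states; ASCII gel rendering.
7. **`marker_eval`** — per-marker verdicts (informative at the smallest
   resolving gel %, z_only, unresolvable, partial_copy_only, not_found,
   confounded), conservative sex calls, per-species marker ranking.
8. **`synthetic_data`** — a ZW genome simulator with planted ground truth
   (gametolog divergence, signed intron indels, degenerate-site
   realizations, decoy and truncated copies), plus packaged worked-example
   fixtures.

A `zwmarker` CLI (`simulate`, `structure`, `pcr`, `search`, `gel`,
`report`) wraps the library; every output file carries the producing
version and a parameter hash, and reruns are byte-identical.

## Worked example

The packaged worked-example fixture reproduces a published seven-marker
panel (M1–M7, primer pairs P2/P8, 1272H/1237L, CHD1i9, 2550F/2718R,
CHD1i16, USP1/USP3, NIPBLi16) on a synthetic turaco-like genome whose
gene layout places every primer footprint at its reported coordinate:

```python
from zwmarker import run_pipeline
from zwmarker.synthetic_data import paper_fixture
from zwmarker.marker_eval import recommend_panel

fx = paper_fixture()
res = run_pipeline(fx.records, fx.mrnas, fx.primer_pairs, fx.role_map,
                   species_id="turaco")
for m in sorted(res.verdicts):
    v, rep = res.verdicts[m], res.copy_reports.get(m)
    second = (f"{rep.second_length} bp on {rep.second_location}"
              if rep and rep.second_length else "absent")
    print(f"{m}: Z={v.z_length or '-'} second={second} dL={v.delta_l} "
          f"-> {v.verdict}"
          + (f" @{v.gel_pct_required:g}%" if v.gel_pct_required else ""))
print("recommended:", [p.marker_id for p in
                       recommend_panel(res.verdicts.values())["turaco"]])
```

prints

```
M1: Z=367 second=378 bp on scaffold dL=11 -> informative @3%
M2: Z=258 second=269 bp on scaffold dL=11 -> informative @3%
M3: Z=2997 second=623 bp on scaffold dL=2374 -> informative @1%
M4: Z=504 second=461 bp on scaffold dL=43 -> informative @1%
M5: Z=464 second=421 bp on scaffold dL=43 -> informative @1%
M6: Z=- second=absent dL=None -> not_found
M7: Z=923 second=510 bp on W dL=413 -> informative @1%
recommended: ['M3', 'M7', 'M4', 'M5', 'M1', 'M2']
```

Reading the output: the M1/M2 intron-22 markers have an 11 bp polymorphism
that only a 3% gel separates — usable in principle, impractical on a
routine 1–2% gel. The NIPBL intron-17 marker M7 (923 vs 510 bp) separates
on a 1% gel — within 10 minutes of electrophoresis, per
`min_gel_percent(923, 510, time=10)`. M6 (SPIN) finds no binding sites at
all. M3 tops the raw ranking by sheer ΔL, but feed its real-world ~600 bp
nonspecific band into `evaluate_marker(..., nonspecific_lengths=[600])`
and it drops to `confounded`, leaving M7 the recommended marker — with
M3 as the fallback for a species whose W copy of M7 is absent (a `z_only`
verdict).

The same run from the shell:

```sh
zwmarker simulate --seed 7 --out sim/          # random condition + truth.json
zwmarker report --genome sim/genome.fasta --mrna sim/mrna.fasta \
    --primers sim/primers.tsv --roles sim/roles.yaml \
    --truth sim/truth.json --species SX --out rep/
zwmarker gel --lengths 923,510 --pct 1 --time 10
```

Real assemblies are supported the same way — point `--genome` at a FASTA
(e.g. GenBank assemblies GCA_000709365.1 / GCA_009769465.1 for the male
and female red-crested turaco) with a role map naming the Z/W/scaffold
sequences, and `--mrna` at the gene transcripts (XM_009991467.1,
XM_009988563.1, XM_009984506.1). Nothing in the package or its tests
downloads anything.

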