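# sdrpred

Pan-specific prediction of HLA class II (DR) peptide binding and CD4+
T-cell epitopes through **specificity-determining residues (SDRs)**.

## The problem

CD4+ T cells recognize peptides displayed by HLA class II molecules, and
epitope-based vaccine design needs to know which peptides of an antigen a
given HLA-DR variant will present. The DR locus is enormously polymorphic
— hundreds of distinct protein variants (allotypes) — while experimental
binding data exist for only a few dozen of them. A *pan-specific* method
must therefore generalize: predict binding for allotypes that have no
binding data of their own.

`sdrpred` does this by exploiting the structure of the binding groove.
The groove presents five pockets (P1, P4, P6, P7, P9), each engaging one
anchored residue of the nonameric binding core, and the peptide
preference of each pocket is determined by a small set of polymorphic
β1-domain positions — the SDRs. Two allotypes with similar SDRs at a
pocket are assumed to share that pocket's preference, so high-affinity
binding data can be transferred between them pocket by pocket.

## The model

For a query allotype *q* and each pocket *P*:

1. Read *q*'s SDR residues at *P* off its β1 sequence (the pocket → β
   position map is a user-editable configuration; the shipped default
   covers 15 DRB1-numbered positions).
2. Pool the nonameric high-affinity binding cores (IC50 ≤ 50 nM) of every
   database allotype whose SDR string at *P* is similar to *q*'s —
   similar meaning every aligned residue pair scores strictly positive in
   BLOSUM62.
3. Estimate residue frequencies at the pocket's anchored core position
   with pseudocounts, f̂ₐ = (cₐ + n/20)/(2n), where cₐ is the residue
   count and n the pool size, and form log-odds weights
   wₐ = log(f̂ₐ / pₐ) against a background composition pₐ (uniform 1/20
   by default).

A nonamer's raw score is the sum of its five anchored-residue weights.
Raw scores are mapped linearly onto [1, 100] using the matrix's
theoretical minimum and maximum nonamer scores; a normalized score ≥ 60
calls a binder. Antigens are scanned with a sliding nonamer window
(L − 8 windows for a protein of length L).

The database is built from variable-length ligands by filtering
(length ≥ 9, standard residues, ≤ 50% alanine, non-whole-cell assays,
IC50 ≤ 50 nM) and aligning each allele's ligands to a common nonamer
register with a Gibbs sampler. The evaluation module implements
leave-one-allele-out cross-validation with balanced resampled AUCs,
per-protein negative construction, high-specificity fractional AUC, and
the epitope ranking-percentage metric. A synthetic-fixture module
generates complete, reproducible test worlds (allotype panels with
designed SDR sharing, sampled cores, planted epitopes) so the entire
pipeline can be exercised without external data.

## Worked example

Simulate a panel of four allotypes in which consecutive pairs share all
five pockets, build the core database, derive a matrix for the first
allotype, and cross-validate:

```bash
sdrpred simulate cores --n 4 --design paired --cores-per-allele 30 --seed 11 --out sim
sdrpred build-db --records sim/records.tsv --hla sim/alleles.fasta \
                 --sdr-config sim/sdr_config.json --seed 11 --out db
sdrpred predict --allele "DRB1*90:01" --db db --out pwm.tsv
sdrpred evaluate --db db --repeats 10 --seed 1 --out report.tsv
```

which prints:

```
120 records -> sim
120 cores over 4 alleles -> db
PWM for DRB1*90:01: s_min=-3.466 s_max=8.104 -> pwm.tsv
mean per-allele AUC 0.992, pooled AUC 0.992 -> report.tsv
```

`s_min`/`s_max` are the theoretical nonamer score bounds that anchor the
1–100 normalization. The cross-validation report (`report.tsv`) shows
each allele predicted from the *other* alleles' data alone, with
balanced AUC ≈ 0.99 because every allele has an SDR-identical partner:

```
allele      n_pos  mean_auc  sd       frac_auc_0.8  evaluable
DRB1*90:01  30     0.998333  0.00191  0.197407      True
DRB1*90:02  30     0.986667  0.00319  0.184444      True
...
```

Scanning antigens with planted epitopes recovers them at the top of the
ranking — including in the antigen of the SDR-similar partner allotype,
which is the pan-specific transfer at work:

```bash
sdrpred simulate antigen --n 4 --design paired --protein-len 150 --seed 11 --out ag
sdrpred scan --pwm pwm.tsv --antigens ag/antigens.fasta --cutoff 60 --out hits.tsv
```

```
protein_id   offset  nonamer    raw      normalized  binder
antigen_000  30      MSSISDHSA  8.10375  100         True
antigen_001  89      MSSISDHSA  8.10375  100         True
```

`antigen_000` carries the planted epitope for DRB1\*90:01 at offset 30;
`antigen_001` belongs to its SDR-sharing partner. The antigens of the
two dissimilar allotypes yield no binder calls with this matrix.

Everything is also available as a library — see `sdrpred.hla`,
`sdrpred.binding_db`, `sdrpred.pwm`, `sdrpred.scan`,
`sdrpred.evaluation` and `sdrpred.simulate`.

## Scope

DRB1/DRB3/DRB4/DRB5 only — DQ and DP groove specificity involves both
chains and is not modelled. The structural pipeline that originally
identified SDR positions (contact analysis of crystal structures) is out
of scope: the position map is consumed as configuration. See
`docs/methods.md` for the model's assumptions and limitations.
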