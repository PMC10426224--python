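# safescreen

Tiered allergenicity/toxicity sequence screening for transgenic gene
products, plus an E-value-gated guide-RNA-vs-microRNA screen and a decoy
database generator for closed-loop validation.

The screens implemented:

1. **Full-length homology** — exact Smith–Waterman/Gotoh local alignment of
   the query protein against every database entry (BLOSUM62, gaps 11/2 by
   default), with candidate hits gated at E ≤ 10 and significance called by
   the Codex-style rule: ≥35% identity over ≥80 alignment columns (gap
   columns included in both the identity denominator and the length).
2. **Sliding 80-mer windows** — every stride-1 window of the query aligned
   against every entry, flagged under the same 35%/80 rule.
3. **Exact k-mer epitope scan** — every contiguous 8-mer (6-mer optional) of
   the query matched exactly against every entry; matches are reported
   unconditionally.
4. **RNA screen** — local alignment of a guide RNA (both strands, +5/−4
   nucleotide scoring, gaps 10/6) against a microRNA set, significant below
   E < 0.01.

E-values use the Karlin–Altschul form `E = K·m·n·exp(−λS)` with published
gapped (λ, K) for the shipped schemes and no composition or effective-length
adjustment, so results are deterministic and oracle-testable. This is a
documented divergence from heuristic engines (BLASTP/COMPASS/FASTA36):
scores and identities are exact optima, but E-values will not numerically
match composition-adjusted BLAST output.

Because the real reference repositories (UniProtKB keyword sets, COMPARE,
AllergenOnline, miRBase) are not redistributable, `safescreen.synth`
generates decoy databases with controlled structure: planted homologous
segments at an exact ungapped identity, planted k-mer epitopes at known
offsets, and mono-/dinucleotide-shuffled RNA decoys, all fully seeded with a
JSON manifest of every planted signal.

The four query/subject sequences used throughout the tests (hCas9 1423 aa,
DsRed 226 aa, Hev b 9 enolase 445 aa, T1 gRNA 96 nt) ship as FASTA fixtures
under `src/safescreen/data/` and load via `safescreen.load_fixture(name)`.

## Command line

```bash
# three-tier allergen screen (full-length + windows + epitopes + verdict)
safescreen allergen --query hcas9.faa --db allergens.faa --out-prefix run1

# full-length toxin screen producing table-style report rows
safescreen toxin --query hcas9.faa --db toxins.faa --out-prefix run1

# guide RNA vs microRNA screen (use --spacer-only for the 5' spacer alone)
safescreen rna --query t1_grna.fna --db mirnas.fna --out-prefix run1

# decoy database with a planted homolog and epitope
safescreen decoys --n-records 50 --seed 7 \
    --plant-homolog donor.faa:0.45:100 --plant-epitope EHIANLAG:3 \
    --out-prefix decoys
```

Defaults reproduce the reference settings (BLOSUM62 11/2, k = 8, window 80,
35%/80 rule, E ≤ 10 protein / E < 0.01 RNA). Precedence is CLI flag >
`--config` file (flat `key = value`) > built-in default. Every TSV output
starts with `#` comment lines recording the tool version, the resolved
configuration and SHA-256 checksums of the inputs; JSON outputs carry the
same data under `_provenance`.

## Layout

- `safescreen.seqio` — validated FASTA I/O (protein/dna/rna alphabets)
- `safescreen.align` — Smith–Waterman/Gotoh, scoring schemes, percent
  identity, Karlin–Altschul E-values
- `safescreen.allergen` — window counting, k-mer epitope scan, sliding
  window screen, full-length allergen screen
- `safescreen.toxin` — full-length toxin screen and the structured verdict
- `safescreen.rna` — guide-RNA vs microRNA screen
- `safescreen.synth` — decoy databases, identity-controlled mutation,
  RNA shuffles
- `safescreen.report` / `safescreen.cli` — report serialization and the
  `safescreen` command
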