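# svatk — sequence-variant-analysis post-processing toolkit

Recombinant protein therapeutics carry low-level *sequence variants* (SVs):
unintended single amino-acid substitutions from DNA mutations or
translational misincorporation, typically present at 0.1–1% of the product.
Peptide-map LC-MS/MS can detect them, but a variant database search over a
deep tryptic/Asp-N/thermolysin map produces hundreds of candidate hits, most
of them false positives, each of which costs an analyst manual review time.

`svatk` is the post-search half of that workflow, for MS scientists and
analysts doing SV characterization of biotherapeutics. It takes search-engine
PSM exports (as a neutral CSV schema) plus the protein FASTA and provides:

- **In-silico digestion** — trypsin (C-side of K/R, proline-suppressed),
  Asp-N (N-side of D) and thermolysin (N-side of A/F/I/L/M/V, unlimited
  missed cleavages), fully specific and semi-specific enumeration.
- **Delta-mass arithmetic** — monoisotopic substitution shifts
  Δ = m(obs) − m(wt) and exhaustive isobaric-conflict lookup (e.g. Ala→Glu,
  Gly→Asp and cysteine carboxymethylation all sit at +58.0055 Da; a heavy
  ¹³C₂ iodoacetic acid label moves the alkylation to +60.0122 Da and breaks
  the degeneracy).
- **Four-rule false-positive triage** — annotates (never deletes) each
  candidate: R1 semi-tryptic peptides whose variant does not involve K/R;
  R2 mass shifts equal to a residue mass with that residue near a peptide
  terminus; R3 below the quantification limit; R4 orthogonal-digest calls
  redundant with confident tryptic coverage — plus score and MS1
  mass-error gates, and score-cutoff sweeps for calibration.
- **Relative quantitation** — per variant,
  100·A_v/(A_v + A_wt) from XIC areas summed over charge states and
  enzymes, with automatic wildtype-peptide pairing.
- **Run comparison reporting** — unique-variant-peptide accounting and
  half-up-rounded percent reduction between workflows.
- **A seeded simulator** — synthetic spiked-variant peptide maps with a
  truth table (true SVs at fractional-percent levels plus planted false
  positives of all four classes), and a phenomenological DDA acquisition
  model that reproduces the injection-time-gating bias by which an
  aggressive space-charge threshold inflates dominant-ion signal ~2× and
  under-quantitates co-eluting low-level peptides (0.5% spikes reading
  ~0.3%); raising the threshold to 100 ppm restores unbiased recovery.

## Worked example

Generate the default synthetic project (7 true SVs spiked at 0.2% with best
scores ≥ 225, and 50 planted false positives) and run the pipeline:

```sh
svatk simulate project --seed 1 --out-dir demo
svatk run --psms demo/psms.csv --fasta demo/project.fasta \
    --label sva7 --out-dir demo/run
```

`demo/run/report.md` then contains:

```
| metric | value |
| --- | --- |
| PSMs | 128 |
| variant PSMs | 64 |
| unique variant peptides (before triage) | 57 |
| unique variant peptides (retained) | 7 |
| retained variant sites | 7 |
```

and a Rel. Quant table, e.g. `| G6A_LC | 0.2 | 2 | 232.962 |`: variant
G6A on the light chain quantified at 0.2% of the peptide pool from 2
retained PSMs with best score 233. All 57 candidate variant peptides
collapse to exactly the 7 planted true variants; every planted false
positive is annotated with the rule that caught it (see the `comment`
column of `demo/run/psms_annotated.csv`). Sweeping the score cutoff:

```sh
svatk sweep --psms demo/psms.csv --fasta demo/project.fasta \
    --cutoffs 200,225,250,300 --out demo/sweep.csv
```

shows 7 variant sites retained at cutoff 225 but only 4 at 250 — three
true variants have best scores in [225, 250), which is why 225 is the
calibrated cutoff for a 0.2% detection requirement.

## Layout

- `src/svatk/chem.py` — residue/modification masses, substitution deltas,
  isobaric partners
- `src/svatk/digestion.py` — enzymes, cleavage sites, full/semi digestion,
  FASTA I/O
- `src/svatk/psm_io.py` — PSM CSV schema, variant-call names, YAML config
  profiles (`high_res`, `legacy`)
- `src/svatk/triage.py` — the four rules, gates, `triage_run`, sweeps
- `src/svatk/quant.py` — wildtype pairing and relative quantitation
- `src/svatk/simulate.py` — acquisition model and synthetic projects
- `src/svatk/report.py` — accounting and markdown reports
- `src/svatk/cli.py` — `svatk digest|triage|quant|sweep|simulate|report|run`

See `docs/methods.md` for the models, parameter choices and limitations.
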