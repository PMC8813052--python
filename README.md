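# idrkit

Sequence informatics for intrinsically disordered regions (IDRs): amino-acid
composition and heatmap matrices, Shannon sequence complexity, Kyte–Doolittle
hydropathy, charge patterning (FCR, NCPR, sigma, Das–Pappu kappa, isoelectric
point), sliding-window tracks and run-length statistics, CDK consensus-site
scanning, proteome-scale disorder-track segmentation, and composition-preserving
sequence-variant designers (scramble, uniform-charge redistribution, residue
substitution, deletion) with dotplot verification.

The package ships the eleven Cdt1 IDR construct sequences used throughout its
test suite as FASTA fixtures (`idrkit.load_fixture("WT")`, `"ScrIDR"`,
`"Uniform"`, ...), plus a synthetic-data module that generates seeded proteomes
with known ordered/disordered block structure so the whole pipeline is testable
offline.

## Library overview

| Module | Contents |
| --- | --- |
| `idrkit.sequence_io` | `ProteinRecord`, `Region` (1-based inclusive), FASTA I/O, `extract_region`, packaged fixtures |
| `idrkit.composition_metrics` | `aa_composition`, `composition_matrix`, `shannon_complexity` (natural log, range 0–ln 20), `mean_hydropathy`, `fraction_of_set`, `composition_percent_difference` |
| `idrkit.charge_patterning` | `classify_charge` (K/R +, D/E −, H neutral), `fcr`, `ncpr`, `blob_decompose`, `kappa` (overlapping blobs g = 5, 6), `isoelectric_point` (Henderson–Hasselbalch bisection, Bjellqvist pKa set in `PKA`), `compute_charge_metrics` |
| `idrkit.local_windows` | `ncpr_track`, `fraction_track`, exact-rational `count_windows_at_or_above`, `merged_regions_at_or_above`, `run_length_partition` (1 / 2 / 3+ classes), `scan_cdk_sites` ([S/T]P and [S/T]PX[R/K]) |
| `idrkit.disorder_segmentation` | `smooth_track` (centered truncated moving average), `segment_track` (threshold 0.5, strict length cutoff), `summarize_proteome` (150-aa complexity cutoff, 100-aa feature cutoff), `percentile_of`, `surrogate_disorder_scores`, score TSV I/O |
| `idrkit.variant_design` | `scramble`, `design_uniform_charge` (seeded kappa-lowering local search), `substitute`, `delete_region`, `dotplot` (BLOSUM62, window 15, threshold 32) |
| `idrkit.synthetic_data` | `sample_sequence`, `generate_proteome` (block architecture + noisy indicator tracks + ground truth), `kappa_ladder` (monotone segregation ladders) |
| `idrkit.cli` | click CLI and the `SequenceProfile` bundle |

Example:

```python
from idrkit import load_fixture
from idrkit import charge_patterning as cp, composition_metrics as cm

wt = load_fixture("WT")
print(cm.shannon_complexity(wt).entropy)   # 2.684…
print(cp.kappa(wt))                        # 0.1988…
print(cp.isoelectric_point(wt))            # 10.11…
```

## Command line

```sh
idrkit profile constructs.fasta --out profiles          # TSV + JSON metric table
idrkit proteome proteome.fasta --scores scores.tsv --out-dir run/
idrkit proteome proteome.fasta --surrogate --out-dir run/
idrkit design scramble input.fasta --seed 7 --out scr
idrkit design uniform input.fasta --seed 1 --out uni    # kappa <= 0.07 target
idrkit design substitute input.fasta --from-set F --to-residue L --out f2l
idrkit design delete input.fasta --region 1-100 --out d1
idrkit synth --n-proteins 100 --seed 0 --out-dir synth/ # FASTA + scores + truth
```

Exit codes: 0 success, 1 usage error, 2 partial batch failure (e.g. proteins
skipped for missing or mismatched score tracks). Disorder scores are read from
TSV — either `protein_id  position  score` or per-protein two-column files —
with positions 1..L; the package never invokes an external predictor.

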