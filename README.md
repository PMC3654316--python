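# reflexio

Standalone, testable re-implementation of the decision and statistics stages
of an automatic macromolecular-crystallography data-reduction pipeline:

- **Shell statistics** — equal-reciprocal-volume resolution binning;
  completeness, 〈I/σ〉, R-merge, R-meas, multiplicity per shell.
- **Automatic high-resolution limit** — low→high shell-retention loop with
  linear 〈I/σ〉-vs-resolution interpolation at the failing shell
  (defaults: 〈I/σ〉 cutoff 2, outer-shell completeness cutoff 80%).
- **Wilson outlier rejection** — Wilson-plot fit, Z > 10 rejection list
  (REMOVE.HKL-style) and a single re-merge pass.
- **Grouped multi-position merging** — lattice-consistency screening,
  reference-dataset selection, indexing-ambiguity resolution by intensity
  correlation, single-factor rescaling, and incremental merged statistics.
- **Anomalous triage & SAD planning** — per-shell 〈d″/σ(d″)〉 with a 1.3
  submission trigger, Matthews molecular-weight estimate at 47% solvent,
  a 3-solvent × 2-hand trial grid, and the strict CC > 25% /
  fragment-length > 10 solved-structure flag.
- **Spot-wedge acquisition planning** — 20-image first wedge plus a
  10-image second wedge ideally 90° from the start, relaxed in 5° steps.
- **Synthetic data** — Wilson-distributed intensities with B-factor
  falloff, counting-statistics noise, injectable outliers, Friedel
  differences, and grouped sub-datasets, so the whole pipeline is testable
  offline.

Everything operates on plain-text unmerged reflection files (an
XDS-ASCII-style dialect or TSV); no image integration is performed and no
external crystallography programs are invoked.

## Command line

```sh
reflexio fast INPUT.hkl --outdir out           # statistics, rejection, cutoff, both Friedel branches
reflexio full INPUT.hkl --outdir out           # same, over all metric-compatible candidate lattices
reflexio group-merge MANIFEST --group P222     # merge sub-datasets listed one path per line
reflexio sad-triage INPUT.hkl                  # anomalous shells, trigger, trial plan
reflexio assess RESULTS.txt                    # flag successes from 'cc fragment_length' lines
reflexio plan-wedges --n-images 360            # spot-wedge plan
reflexio gen --cell 30,40,50 --group P222 ...  # synthetic dataset + truth JSON
```

User cutoffs are exposed as flags (`--d-min`, `--i-sigma-cutoff`,
`--completeness-cutoff`, `--shells`). Reports land in the output directory:
`summary.xml` (validated against the bundled structural schema),
per-shell TSVs, a removal list, an increments TSV for grouped runs, and a
run log. Report files contain no timestamps, so reruns are byte-identical.

## Conventions and known limitations

- Symmetry support is a minimal explicit-matrix registry
  (`src/reflexio/data/symmetry_groups.txt`), one group per Laue class of
  interest, with indexing-ambiguity coset representatives stored per entry.
  Full space-group machinery is out of scope.
- Systematic absences are not removed from completeness denominators
  (small known bias for screw-axis/centred groups).
- All reflections are treated as acentric in the Wilson model.
- Per-dataset scaling in grouped merging is a single multiplicative factor;
  full scaling (per-image, B-factor) is out of scope.
- The resolution interpolation is linear in d; 〈I/σ〉 is computed on
  unmerged observations by default (merged variant behind a flag).
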