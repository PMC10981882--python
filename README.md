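# needleplace

Accuracy assessment of image-guided needle placement against a target nerve,
as a tested, reusable pipeline:

1. **mesh_io** — binary/ASCII STL reading and writing, plus deterministic
   barycentric-grid surface sampling at a configurable maximum spacing
   (units: mm throughout).
2. **synthetic** — a synthetic phantom-trial generator: a curved nerve tube
   (default 75 mm × 2 mm) and a straight cylindrical needle placed at exact,
   configurable lateral/depth offsets, with per-trial rigid pose jitter,
   surface noise, six named pelvic-style landmarks, and full ground truth —
   so every downstream stage is verifiable without scanned data.
3. **registration** — closed-form rigid Procrustes on the six named
   landmarks, point-to-point ICP (reflection-free, monotone RMS), and rigid
   transform utilities.
4. **metrics** — per trial: total-least-squares needle-axis fit, extraction
   of the outermost 5.00 mm active tip, and the three distances — minimal
   Euclidean tip-to-nerve, lateral (perpendicular nerve-to-axis), and depth
   (axial offset between tip and the foot of the lateral perpendicular) —
   with signed variants (positive lateral = configured "subject's right";
   negative depth = deeper than target).
5. **stats** — cohort summaries: medians and quartiles under the p·(n+1)
   weighted-average convention, percentage of trials within the 5.00 mm
   effective range, Shapiro–Wilk normality gating, and one-sample t /
   Wilcoxon signed-rank tests against 5.00 mm (exact enumeration for small
   tie-free samples, tie- and continuity-corrected normal approximation
   otherwise).
6. **cli** — `needleplace` command-line orchestration with YAML config,
   logging, manifests and deterministic seeded runs.

## CLI

```sh
# generate a synthetic cohort (STL pairs + landmarks + ground-truth table)
needleplace synth --out trials/ --n-trials 40 --seed 7

# run the full analysis: registration, tip extraction, distances, statistics
needleplace analyze --trials trials/ --out results/

# render the summary table and the lateral-vs-depth scatter
needleplace report --results results/ --plot results/scatter.png
```

`analyze` consumes any directory of `<id>_nerve.stl` / `<id>_needle.stl`
pairs (optional `<id>_landmarks.csv` with `name,x,y,z` rows enables the
landmark-based ICP initialization). The first trial (or `--reference`) is
the reference frame; each trial's nerve is ICP-matched onto it and the
fitted transform is applied to the needle. Outputs: `per_trial.csv`,
`summary.csv`/`summary.md`, `scatter.csv`, serialized run config and a
manifest with input checksums. Reruns with the same config and seed are
byte-identical.

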