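# odontomatch

Forensic dental identification compares antemortem (AM) dental records with
postmortem (PM) findings. With intra-oral 3D scanning both sides of that
comparison can be surface meshes, and the comparison itself can be made
objective: superimpose the two scans with iterative closest point (ICP)
registration and read off the residual root-mean-square (RMS) closest-point
distance, in millimetres. Scans of the same person produce a small RMS; scans
of different people a larger one, so a single RMS threshold can separate
matches from non-matches.

The catch is *extraneous data*: gingiva and other soft tissue captured along
with the teeth is far less reproducible than dental hard tissue and inflates
the RMS of true matches. `odontomatch` implements and compares the five
segmentation strategies used to deal with this, including a streamlined
**joint planar slice** in which both scans are superimposed first and a
*single* cutting plane is applied to the combined image, followed by
re-registration — fewer manual steps, and automatable:

| Method | Strategy | When applied |
|---|---|---|
| M1 | none (control) | — |
| M2 | semi-automatic gingival reduction (gingival collar retained) | per image, before ICP |
| M3 | manual gingival reduction (tooth surface only) | per image, before ICP |
| M4 | individual planar slice | per image, before ICP |
| M5 | joint planar slice | both images at once, after initial ICP |

The package is a library plus a CLI. Because no public AM/PM scan corpus
exists, it ships a first-class synthetic dentition generator: labeled
full-arch meshes (14 teeth, FDI numbering, parabolic arch, gingiva band with
interdental papillae), with per-participant shape individuality and an AM→PM
degradation chain (smooth cast deformation, tissue-dependent surface noise,
random rigid placement with known ground truth).

## The comparison engine

Registration is trimmed point-to-point ICP: alternate nearest-neighbour
correspondence (k-d tree) with the closed-form least-squares rigid fit
(Kabsch/SVD), discarding the worst 10% of correspondences each iteration to
bound the influence of non-overlapping capture extent. The reported RMS is

```
RMS = sqrt( mean_i  || T p_i  −  q_{nn(i)} ||² )
```

over the retained PM→AM correspondences of the final iteration. Match
classification is `rms < cutoff`, with the cutoff fitted by the midpoint rule
on separable data (logistic regression degenerates under perfect separation;
the package detects that and says so).

## Worked example

```python
import odontomatch as om

cohort = om.make_cohort(6, seed=101)             # 6 participants, 24 scans
design = om.StudyDesign(methods=["M1", "M2", "M3", "M4", "M5"],
                        replicates_per_cell=1, sessions=1, operators=1,
                        seed=101)
table = om.run_study(cohort, design, icp=om.ICPParams(sample_size=5000))

print(table.groupby(["method", "is_match"])["rms"].mean().round(3))
seg = table[table.method != "M1"]
cut = om.fit_rms_cutoff(seg["rms"], seg["is_match"])
print(f"cutoff {cut.cutoff:.3f} mm, accuracy {cut.accuracy:.0%}")
```

prints (RMS in mm):

```
method  is_match
M1      False       0.434
        True        0.207
M2      False       0.496
        True        0.188
M3      False       0.526
        True        0.188
M4      False       0.487
        True        0.192
M5      False       0.463
        True        0.191
Name: rms, dtype: float64
cutoff 0.282 mm, accuracy 100%
```

Matching pairs sit well below non-matching pairs for every method; every
segmented method lowers the matching RMS relative to the unsegmented control;
and a single threshold between the two distributions classifies all 168
segmented comparisons correctly. The same workflow is available from the
shell:

```bash
odontomatch generate --participants 6 --seed 101 --out-dir scans/
odontomatch compare scans/P1_upper_AM.stl scans/P1_upper_PM.stl --method M5
odontomatch study --participants 6 --seed 101 --out results.csv
odontomatch analyze --in results.csv --out report.json
```

## Scope

Mixed-effects regression modelling of the RMS tables is deliberately out of
scope — the CSV the pipeline emits (participant pair, arch, method,
replicate, session, operator, match status, RMS) is shaped so R's `lme4` /
`emmeans` can consume it directly. Curvature-based gingival margin detection
on unlabeled real scans, tooth-by-tooth segmentation, and DICOM/CT import are
likewise out of scope. See `docs/methods.md` for the model details,
parameter defaults, and known limitations.
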