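# mds-curate

Curation toolkit for hospital imaging research datasets. It automates the
life cycle of a structured medical dataset — from a loose pile of exported
NIfTI volumes to a navigable patient tree, through pseudonymized extraction
for annotation and AI training, to re-integration of manually corrected
ground-truth labels — and provides the standard segmentation-quality
metrics for evaluating AI predictions against ground truth.

It is written for data curators and research engineers who manage imaging
cohorts inside a secured hospital environment, where every export must be
either fully anonymized (no link back to the patient exists) or
de-identified (a re-linking key is retained inside the secure system).

## The data structure

Every file is named `<Patient>_<Acquisition>_<Phase>_<Tag>.<ext>`, e.g.
`H001_CT001_Porto_IM.nii.gz`: patient H001, first CT acquisition,
portal-venous phase, the image itself. Labels replace the `IM` tag with a
structure code (`LP` liver parenchyma, `HV` hepatic vein, `PV` portal vein,
`LV` liver veins combined, `LL` liver lesion, `BD` bile duct). The name
alone determines the file's slot in a four-level tree, in the spirit of the
Brain Imaging Data Structure (BIDS):

```
MAIN/                      level 1: dataset root
  H001/                    level 2: patient
    H001.json              de-identified clinical record
    CT001/                 level 3: acquisition (modality + order)
      Porto/               level 4: phase or sequence
        H001_CT001_Porto_IM.nii.gz
        H001_CT001_Porto_LP.nii.gz
```

## The workflow

1. **structure** — move files from a flat drop-off directory into the tree,
   quarantining anything whose name does not parse, and split the clinical
   CSV (one row per patient) into per-patient JSONs.
2. **extract** — serve a request CSV (`Pat,Mod,Phase,Cl 1[,Cl 2,...]`) by
   copying matching files out under `CaseNNN` pseudonyms drawn from a
   seeded random shuffle of 1..N. `anonymize` mode retains no key;
   `deidentify` mode writes the patient↔Case key log.
3. **reintegrate** — map manually corrected, Case-named label volumes back
   to patient names via the key, swap the `IM` tag for the label code, and
   stage them for re-structuring — which files each label next to the image
   it annotates.
4. **evaluate** — compare a predicted label volume against ground truth.

## The metrics

For binary masks GT and Pred on one voxel grid, with TP = |GT ∩ Pred|,
FP = |Pred \ GT|, FN = |GT \ Pred|:

- Dice similarity coefficient DSC = 2·TP / (|GT| + |Pred|), Dice loss = 1 − DSC
- over-segmentation OS = 2·FP / (|GT| + |Pred|)
- under-segmentation US = 2·FN / (|GT| + |Pred|)

The shared denominator gives the exact identity OS + US = 2·(1 − DSC),
which the implementation asserts on every evaluated pair.

## Worked example

Everything below runs on synthetic data produced by the built-in
generators — no patient data required.

```console
$ mds simulate tree --out src --patients 7 --seed 7
wrote 21 files to src
$ mds simulate clinical --out src/clinical.csv --patients 7 --columns 5
wrote 7 rows to src/clinical.csv
$ mds structure --source src --main MAIN --clinical-csv src/clinical.csv
moved=21 quarantined=0 dirs_created=21 json_written=7
$ mds extract --main MAIN --request request.csv --out EXPORT \
      --mode deidentify --key key.csv --seed 11
copied=3 missing=0 patients=3
$ cat key.csv
# seed=11
Pat,Mod,Phase,Cl 1,Ns
H001,CT001,Porto,IM,Case002
H002,CT001,Porto,IM,Case001
H003,CT001,Porto,IM,Case003
$ mds reintegrate --corrected EXPORT --key key.csv --staging STAGING --tag LL
staged=3 skipped=0
$ mds structure --source STAGING --main MAIN
moved=3 quarantined=0 dirs_created=0 json_written=0
```

21 volumes (7 patients × image + two labels) were filed into the tree and
7 clinical JSONs written. The three requested images went out under
shuffled pseudonyms (note Case002 for H001 — the export order is unrelated
to the request order), came back as "corrected" labels, and were re-filed
next to their source images as `*_LL.nii.gz`.

Metric evaluation on a generated pair with known confusion counts:

```console
$ mds simulate masks --out-gt gt.nii.gz --out-pred pred.nii.gz \
      --tp 900 --fp 50 --fn 100 --seed 1
$ mds evaluate --gt gt.nii.gz --pred pred.nii.gz
{
  "dsc": 0.9230769230769231,
  "dice_loss": 0.07692307692307687,
  "over_seg": 0.05128205128205128,
  "under_seg": 0.10256410256410256,
  "tp": 900,
  "fp": 50,
  "fn": 100
}
```

With |GT| = 1000 and |Pred| = 950: DSC = 1800/1950 ≈ 0.9231,
OS = 100/1950 ≈ 0.0513, US = 200/1950 ≈ 0.1026, and
OS + US = 2·(1 − DSC) holds exactly.

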