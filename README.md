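# gliocircuit

Electrophysiology and statistics for studies of glioma–neural-circuit
interactions. Gliomas functionally integrate into cortical networks:
tumour-infiltrated cortex can remain speech-active, intratumoural regions
differ in their resting-state functional connectivity, and tumour cells
co-cultured with neurons reshape network firing. `gliocircuit` packages the
signal-processing and statistical machinery such studies need as a tested,
reusable pipeline, exercisable end-to-end on built-in synthetic data with
recorded ground truth — no patient data required.

## Who it is for

Researchers analysing intraoperative ECoG, resting-state MEG source
reconstructions, in-vitro multi-electrode-array (MEA) recordings, or the
clinical statistics that accompany them, who want the individual analysis
stages as composable, validated functions.

## What it computes

**Speech-locked high-gamma power (`gliocircuit.ecog`).** Channels are screened
by sample kurtosis (Pearson convention, cutoff 5.0); electrodes within 10 mm
of the necrotic tumour core are labelled tumour contacts; trials with
incorrect or >2 s-delayed responses are discarded; epochs span ±2 s around
speech onset. High-gamma power is

HGp(t) = |𝓗{x_bp(t)}|² ,

the squared analytic-signal envelope after common-average referencing,
0.1 Hz high-pass and a zero-phase 300-order FIR band-pass at 70–110 Hz. An
ERSP variant yields the 70–170 Hz envelope, Gaussian-smoothed, resampled to
100 Hz and z-scored per trial.

**Word-frequency decoding (`gliocircuit.decoding`).** An L2-regularized
logistic regression (C = 1) classifies low- vs high-frequency-word trials
from high-gamma envelope features under leave-one-participant-out
cross-validation, with exact binomial (primary) and normal-approximation
significance against chance.

**Imaginary-coherence connectivity mapping (`gliocircuit.megconn`).** For
voxel time series on an 8-mm grid, the coherency C_xy(f) =
S_xy/√(S_xx S_yy) is estimated by Welch segmentation and the alpha-band
(8–12 Hz) imaginary coherence IC = ⟨|Im C_xy(f)|⟩_f taken as the coupling
measure — insensitive to zero-lag (volume-conducted) mixing. Per voxel, the
Fisher-transformed mean IC to the rest of the brain is standardized into a
z-connectivity, tested two-tailed against the contralesional reference, and
split into tertiles: upper = HFC (high functional connectivity), lower =
LFC. Tumours containing ≥1 HFC voxel are HFC-positive.

**Aperiodic-corrected gamma power (`gliocircuit.spectral`).** Thomson
multitaper spectra (29 Slepian tapers, NW = 15) over 1–50 Hz; the aperiodic
background is fit in semi-log space as a Lorentzian

log₁₀ P(f) = b − log₁₀(k + f^χ) ,

with iterative peak masking, and gamma power is the mean 30–50 Hz log-residual
after subtracting it, regressable on intratumoural HFC node counts.

**MEA analytics (`gliocircuit.mea`).** Spike detection at 5 SD of the
(median-based) noise estimate on 200–3,000 Hz band-passed traces; active
channels at ≥5 spikes/min; bursts as runs of ≥5 spikes with inter-spike
intervals ≤100 ms; network bursts as burst-interval unions covering ≥35% of
active electrodes with ≥50 spikes; firing-rate summaries (MFR, wMFR) and
cross-correlogram synchrony (AUNCC).

**Clinical statistics (`gliocircuit.stats`).** Random-intercept linear mixed
model for the tumour vs normal-cortex HGp contrast (participants as random
effects, REML), Benjamini–Hochberg FDR, extent of resection
(pre − post)/pre × 100%, two-sided OLS regression, and Kaplan–Meier curves
with two-tailed log-rank tests.

**Synthetic data (`gliocircuit.synthdata`).** Seeded generators for every
input class — task-locked ECoG with tissue/condition effects, phase-lagged
coupled alpha oscillators on a mirror-symmetric voxel grid with a
coupling-boosted lesion, Poisson/bursting spike rasters with scheduled
network bursts and optional raw voltage, closed-form aperiodic spectra, and
right-censored survival cohorts. Each generator is a pure function of its
spec (same seed ⇒ bitwise-identical data) and returns the ground truth
needed to score downstream stages.

## Worked example

Simulate a mirrored 200-voxel grid whose first 10 voxels ("lesion") carry a
3× boosted share of the common alpha source, then map connectivity:

```python
import numpy as np
from gliocircuit import synthdata, megconn

spec = synthdata.VoxelSimSpec(
    n_voxels_per_hemisphere=100,
    lesion_voxel_ids=tuple(range(10)),
    lesion_coupling_boost=3.0,
    seed=11,
)
vs = synthdata.generate_voxel_dataset(spec)
cmap = megconn.connectivity_map(vs)
lesion = np.asarray(vs.tumour_mask)
count, positive = megconn.count_hfc_in_tumour(cmap.conn_class, lesion)
print(f"lesion classified HFC:  {(cmap.conn_class[lesion] == 'HFC').sum()}")
print(f"HFC voxels in tumour:   {count}  (HFC-positive: {positive})")
print(f"median z-conn, lesion:  {np.median(cmap.z_conn[lesion]):.2f}")
print(f"median z-conn, normal:  {np.median(cmap.z_conn[~lesion]):.2f}")
```

prints

```
lesion classified HFC:  10
HFC voxels in tumour:   10  (HFC-positive: True)
median z-conn, lesion:  4.00
median z-conn, normal:  -0.26
```

All ten boosted voxels land in the upper connectivity tertile (HFC), so the
simulated tumour is HFC-positive; their z-connectivity sits ~4 SD above the
across-voxel mean while normal voxels centre near zero.

The same flows run from the shell: `gliocircuit run --seed 7 --out demo/`
executes simulate → ecog → decode → connect → spectra → mea → stats and
writes CSV/NIfTI/JSON products plus a full-provenance `report.json`;
`gliocircuit connect --seed 7 --out demo/` runs a single stage with its
upstream dependencies. Identical config and seed reproduce every output
byte for byte.

## File formats

Recordings and voxel series use a documented HDF5 layout (`/signal`, `/fs`,
`/channels/{id,coord,tissue}`; `/series`, `/grid_index`, `/mirror_pair`, …);
EDF import is supported for raw signals. Spike tables and cohorts are plain
CSV; connectivity maps are written both as tidy CSV and as one NIfTI volume
per field with the 8-mm grid affine. See `gliocircuit.io`.

## Scope

The package starts from voxel-level source time series and event tables: MEG
beamforming/source reconstruction, MRI segmentation and registration, and
the study-side sequencing pipelines are out of scope, as are vendor raw
formats (CTF, Axion). See `docs/methods.md` for the model details, parameter
defaults, design decisions and known limitations.
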