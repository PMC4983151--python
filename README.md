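# transcallosal

High-resolution trans-callosal structural connectivity analysis and
virtual-callosotomy simulation.

The package maps tractography streamline endpoints onto triangulated
cortical surfaces (nearest-vertex, KD-tree accelerated), summarises the
result as per-triangle median count fields (`log(1 + n)` display),
quantifies hemispheric coverage and per-resting-state-network
involvement, subdivides a corpus-callosum mask into equal fifths along
its principal eigendirection, and predicts per-network disruption under
progressively larger anterior resections, including downsampling from a
17-network to a 7-network parcellation and scan-rescan style Spearman
reproducibility statistics.

Because no subject data ships with the repository, a first-class
synthetic-data generator produces complete input bundles (surfaces, CC
mask, parcellation, tractogram) with para-sagittal termination
concentration, left>right coverage asymmetry and per-network
anterior-posterior CC passage gradients — all with recorded ground truth
so every downstream quantity is verifiable. A small deterministic
fixed-step Euler tracker (anisotropy / 60-degree turning / 10-300 mm
length termination rules, Otsu-based thresholding) is included for
testing the tracking contract.

## CLI

```bash
# synthetic input bundle with planted ground truth
transcallosal generate --seed 1 --n-streamlines 20000 --out bundle/

# full pipeline: assignment, coverage, involvement, vulnerability profiles
transcallosal profile --bundle bundle/ --out results/

# individual stages
transcallosal map --surface-left bundle/surface_left.gii \
    --surface-right bundle/surface_right.gii \
    --tractogram bundle/tractogram.tck --out mapped/
transcallosal segment --mask bundle/cc_mask.nii.gz --out seg/
transcallosal downsample --profile results/profile_17.csv --out profile_7.csv

# paired-session reproducibility (Spearman over per-triangle counts)
transcallosal reproducibility --bundle-a s1/ --bundle-b s2/ --out rho.json
```

Exit codes: 0 ok, 2 validation error, 3 I/O error. A TOML config file can
replace the per-flag inputs (`transcallosal profile --config run.toml`);
flags override config values.

Supported formats: GIFTI / OFF / ASCII-PLY surfaces, TCK (or TRK)
tractograms in RAS mm, NIfTI-1 masks (sform > qform > zooms affine
precedence, voxel-centre convention), plain-text or GIFTI label tables,
CSV for profiles and the editable 17-to-7 network weight table
(`src/transcallosal/data/yeo17_to_7.csv`).

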