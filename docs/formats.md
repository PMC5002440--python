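# File formats

All on-disk formats are plain text or flat binary; every header is listed
here bit-exactly.

## Raw extracellular binary (`.bin` / `.dat`)

Flat binary, little-endian int16, **sample-major / channel-interleaved**:

    frame 0: ch0 ch1 ... chN-1   (one int16 per channel)
    frame 1: ch0 ch1 ...
    ...

File size must be a whole number of `2 * n_channels`-byte frames;
`read_raw` raises `TruncatedFileError` (with byte counts) otherwise. A
0-byte file is a valid empty recording. Conversion to μV multiplies by
`scale_uv_per_bit` (default 0.195 μV/bit). Channel order is the geometry's
`site_ids` order.

## Juxtacellular binary (`juxta.bin`)

Flat binary, little-endian float64, single channel, millivolts, same
sampling rate as the extracellular file.

## Probe geometry CSV

Header: `site_id,x_um,z_um,area_um2`. One row per site; `x_um` lateral,
`z_um` axial (increasing with depth, 0 at the top site).

## Pair metadata CSV

Required header columns: `pair_id,distance_um,depth_um,juxta_threshold`.
Optional: `distance_err_um` (default 10.5). Unknown columns are preserved
in `PairMetadata.notes`. `distance_um` must be ≥ 0; `pair_id` unique.
Pairs `2015_09_04_Pair 5.0` and `2015_09_03_Pair 9.0` are recognized as
negative-first juxtacellular polarity; a `polarity` note column overrides
for other ids.

## Calibration pairs CSV

Header:
`pair_index,ref_x_um,ref_y_um,ref_z_um,mov_x_um,mov_y_um,mov_z_um,theta_deg`.
Reference coordinates are in the stereotaxic frame, moving coordinates in
the tilted manipulator's native frame, `theta_deg` its approach angle.

## Affine correction JSON

Keys: `linear` (3×3 row-major list), `offset_um` (3-vector),
`fit_residual_mean_um`, `fit_residual_sd_um`. The same 12 numbers are also
available flat (row-major matrix then offset) via
`AffineCorrection.to_flat`.

## Pair directory (written by `pairedval simulate` / `simulate_to_dir`)

    extracellular.bin   raw int16 recording (above)
    juxta.bin           float64 juxtacellular trace, mV
    geometry.csv        probe geometry (above)
    true_spikes.csv     header: neuron,sample,time_s,is_juxta_target
    pair_metadata.csv   pair metadata (above)
    manifest.json       package version, seed, config hash, n_channels,
                        rate_hz, scale_uv_per_bit, duration_s

Identical manifests imply bit-identical data files.

## Report directory (written by `pairedval validate`)

    jta.csv        header: t_ms,ch_<id>,...   (μV per channel)
    footprint.csv  header: site_id,x_um,z_um,p2p_uv
    peth.csv       header: bin_center_ms,count
    summary.json   counts, hit/miss statistics, amplitude-distance row
    events.csv     (from `pairedval detect`) header:
                   peak_time_s,peak_channel,n_channels,peak_uv
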