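# Default configuration for the parotid/tumor segmentation pipeline.
# Every value can be overridden; omitted keys fall back to these defaults.

data:
  input_size: 512            # model input plane (pixels)
  sequences: [T1w, T2w, T1wC]  # canonical channel order
  normalization: {mode: minmax_volume}  # per-volume min-max onto [0, 1], midpoint 0.5
  laterality_axis: col       # anatomical-left at high column indices

model:
  in_channels: 3             # follows len(data.sequences)
  out_channels: 4            # left/right parotid, left/right tumor
  input_size: 512
  depth: 4                   # max-pooling stages
  base_filters: 64
  encoder_block_allocation: [2, 2, 2, 3, 3]  # 12 conv blocks over 5 levels
  decoder_blocks_per_level: 2
  gate_source: bottleneck    # attention gating signal from the network bottom
  seed: 0

train:
  learning_rate: 1.0e-4
  optimizer: rmsprop
  epochs: 200
  batch_size: 8
  loss_smoothing: 1.0        # soft-Dice stabilizer
  loss_reduction: batch      # pool Dice sums over the batch (see docs/methods.md)
  folds: 10                  # patient-level cross-validation; validation fraction 1/folds
  seed: 0
  threshold: 0.5             # sigmoid -> binary mask cut
  select_best: false         # evaluate the final epoch, not the best checkpoint

augmentation:                # set to null (or enabled: false) to disable
  gray_scale_range: [0.9, 1.1]    # multiplicative gray disturbance
  gray_shift_range: [-0.1, 0.1]   # additive gray disturbance
  affine_params:
    max_rotation_deg: 10.0
    scale_range: [0.95, 1.05]
    max_translation_fraction: 0.05
  mirror_probability: 0.5    # flip + left/right label swap
  seed: 0
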