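"""Inspect the lightweight 1D-CNN architecture.

Four stride-2 valid convolutions halve the 1,557-point spectrum down to
97 positions at 256 channels; the flattened 24,832 features feed a
500-unit ReLU layer and a linear scalar output. Batch normalization after
each convolution replaces dropout as the regularizer.
"""

from nirquant import build_cnn, dropout_cnn_spec, lightweight_spec, summarize

spec = lightweight_spec()
summary = summarize(spec)

print(f"{'layer':<10}{'channels':>10}{'length':>10}")
for name, channels, length in summary.layer_shapes:
    print(f"{name:<10}{channels:>10}{length:>10}")
print(f"\nflatten size       {summary.flatten_size:,}")
print(f"trainable params   {summary.parameter_count:,}")

model = build_cnn(spec, seed=0)
print(f"built network      {model.n_parameters():,} (must match the analytic count)")

comparator = summarize(dropout_cnn_spec())
print(f"\ndropout comparator {comparator.parameter_count:,} parameters "
      "(no batch-norm scale/shift pairs)")
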