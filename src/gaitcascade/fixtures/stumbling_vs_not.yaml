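# Best published configuration for the stumbling-vs-not node.
# Known inconsistency, preserved as printed: the conv window (10) exceeds the
# window length (4 previous timestamps); the loader clamps it at build time
# and flags the clamp.
name: stumbling_vs_not
n_dense_layers: 11
units_per_layer: [26, 54, 16, 38, 46, 54, 18, 38, 36, 54, 1]
activation_per_layer: [tanh, selu, selu, selu, selu, tanh, selu, selu, selu, tanh, selu]
use_conv: true
conv_filters: 21
conv_window: 10
conv_activation: selu
use_pooling: false
use_lstm: false
learning_rate: 0.01
optimizer: sgd
batch_size: 21
window_length: 4
selected_channels: [P0, P1, P4, P7, P10, P11, P12, P14, A1]
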