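# Best published configuration for the unbalanced-vs-stable node.
# Known inconsistency, preserved as printed: units_per_layer lists 9 entries
# for 11 layers, and two values (5034, 624) fall outside the [1, 64] units
# search bound — almost certainly typographic corruption.  The repaired
# variant below reads the corruption as missing commas (5034 -> 50, 34;
# 624 -> 6, 24), which restores exactly 11 entries, all inside [1, 64].
# The loader builds with the repaired variant and flags the mismatch.
name: unbalanced_vs_stable
n_dense_layers: 11
units_per_layer: [32, 4, 38, 5034, 38, 22, 624, 58, 58]
units_per_layer_repaired: [32, 4, 38, 50, 34, 38, 22, 6, 24, 58, 58]
activation_per_layer: [tanh, tanh, selu, tanh, tanh, tanh, selu, tanh, selu, tanh, selu]
use_conv: true
conv_filters: 6
conv_window: 4
conv_activation: sigmoid
use_pooling: true
use_lstm: false
learning_rate: 0.001
optimizer: adam
batch_size: 19
window_length: 16
selected_channels: [P0, P6, P9, P11, P12, P13, P15, A0]
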