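# Best published configuration for the moving-vs-still node.
name: moving_vs_still
n_dense_layers: 1
units_per_layer: [42]
activation_per_layer: [tanh]
use_conv: false
use_pooling: false
use_lstm: false
learning_rate: 0.01
optimizer: sgd
batch_size: 48
window_length: 32
selected_channels: [P3, P4, P6, P8, P10, P12, P13, A0, A2]
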