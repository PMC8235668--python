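# Best published configuration for the running-vs-walking node.
name: running_vs_walking
n_dense_layers: 3
units_per_layer: [46, 6, 9]
activation_per_layer: [selu, tanh, tanh]
use_conv: false
use_pooling: false
use_lstm: false
learning_rate: 0.01
optimizer: adam
batch_size: 47
window_length: 32
selected_channels: [P1, P3, P4, P6, P8, P11, P12, A0, A2]
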