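# Best published configuration for the standing-vs-seated node.
name: standing_vs_seated
n_dense_layers: 1
units_per_layer: [32]
activation_per_layer: [selu]
use_conv: false
use_pooling: false
use_lstm: false
learning_rate: 0.01
optimizer: adam
batch_size: 33
window_length: 16
selected_channels: [P0, P1, P2, P5, P6, P7, P15, A0]
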