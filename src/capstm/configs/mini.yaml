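# Reduced-width configuration for desk-scale overfitting checks on
# synthetic corpora (tens of pairs, single CPU).
embedding_size: 24
hidden_size: 16
n_capsules: 4
capsule_dim: 8
routing_iters: 3
learning_rate: 0.003
dropout_rate: 0.0
activation: relu
batch_size: 32
max_len: 12
conv_channels: 6
conv_width: 3
conv_dim: 24
norm_mode: softmax
similarity_source: embedding
squash_variant: printed
capsule_mode: routing
use_attention: true
head_hidden: 32
seed: 0
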