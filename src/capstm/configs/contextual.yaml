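# Precomputed 768-dim contextual-vector configuration
embedding_size: 768
hidden_size: 384
n_capsules: 6
capsule_dim: 50
routing_iters: 3
learning_rate: 0.001
dropout_rate: 0.9
activation: relu
batch_size: 32
max_len: 50
conv_channels: 16
conv_width: 3
conv_dim: null
norm_mode: softmax
similarity_source: embedding
squash_variant: printed
capsule_mode: routing
use_attention: true
head_hidden: 100
seed: 0
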