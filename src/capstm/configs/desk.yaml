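# Full five-layer architecture at reduced widths: the configuration used
# for synthetic-corpus generalization experiments on a single CPU.
embedding_size: 32
hidden_size: 32
n_capsules: 6
capsule_dim: 16
routing_iters: 3
learning_rate: 0.002
dropout_rate: 0.1
activation: relu
batch_size: 32
max_len: 16
conv_channels: 8
conv_width: 3
conv_dim: 32
norm_mode: softmax
similarity_source: embedding
squash_variant: printed
capsule_mode: routing
use_attention: true
head_hidden: 64
seed: 0
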