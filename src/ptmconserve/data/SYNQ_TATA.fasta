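>SYNQ_TATA synthetic TatA-like query protein (sequence is randomly generated, not a real protein) OS=Synthetic organism
KWPMRRACNRFYACIAKTACCFFFDHDPCQEGPQCGYPSQQQYNCCFKMACVHRHDFYFR
MVHFHKRRDLYIPKVTPMFAAVWMKLRFF
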