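# Default functional-domain ordering for the 53-component NeuroMark fMRI 1.0
# template: components are listed in contiguous domain blocks, the standard
# presentation order for FNC matrices.  Supply a file with the same layout to
# use a different template or ordering.
domains:
  - name: subcortical
    n_components: 5
  - name: auditory
    n_components: 2
  - name: sensorimotor
    n_components: 9
  - name: visual
    n_components: 9
  - name: cognitive-control
    n_components: 17
  - name: default-mode
    n_components: 7
  - name: cerebellar
    n_components: 4
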