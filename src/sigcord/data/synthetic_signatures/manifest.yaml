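signatures:
- wang76.synthetic.yaml
- cin70.synthetic.yaml
- cin25.synthetic.yaml
- csr.synthetic.yaml
- igs.synthetic.yaml
- t52.synthetic.yaml
- t17.synthetic.yaml
- ggi.synthetic.yaml
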