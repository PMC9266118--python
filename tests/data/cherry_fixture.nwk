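(((EC2|unwounded:0.05,EC9|wounded:0.05):0.25,EC1|unwounded:0.3):0.3,(((EC3|unwounded:0.05,EC10|wounded:0.05):0.25,((EC4|unwounded:0.05,EC11|wounded:0.05):0.1,(EC12|wounded:0.08,EC13|wounded:0.08):0.07):0.15):0.2,(((EC7|unwounded:0.04,EC15|wounded:0.04):0.08,(EC8|unwounded:0.05,EC16|wounded:0.05):0.07):0.08,((EC5|unwounded:0.06,EC6|unwounded:0.06):0.1,EC14|wounded:0.16):0.04):0.3):0.1);
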