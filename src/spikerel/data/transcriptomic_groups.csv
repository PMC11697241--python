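line_label,group
Pvalb,PV
Sst,non-PV inhibitory
Vip,non-PV inhibitory
Htr3a,non-PV inhibitory
Ndnf,non-PV inhibitory
Chat,non-PV inhibitory
Gad2,mixed
Chrna2,mixed
Nkx2.1,mixed
Oxtr,mixed
Cux2,excitatory
Rorb,excitatory
Scnn1a,excitatory
Nr5a1,excitatory
Ntsr1,excitatory
Rbp4,excitatory
Ctgf,excitatory
Tlx3,excitatory
Sim1,excitatory
Esr2,excitatory
Glt25d2,excitatory
Penk,excitatory
Slc17a6,excitatory
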