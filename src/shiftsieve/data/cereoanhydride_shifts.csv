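label,exp,anhydride,acid,carboxylate
C6,170.7,168.7,171.4,172.2
C5,170.4,168.9,172.5,172.4
C7,161.0,156.6,159.1,158.4
C3,137.4,133.9,138.2,140.7
C8,136.2,139.8,139.4,138.2
C12,131.0,132.7,129.8,131.2
C4,124.7,123.5,124.6,123.3
C11,113.1,103.5,112.0,116.6
C10,108.6,115.9,108.1,107.6
C15,87.4,85.6,86.6,85.9
C2,60.4,65.7,59.0,61.6
C9,43.8,47.6,47.6,46.9
C16,26.1,24.8,24.4,26.0
C13,17.6,22.6,17.9,17.8
C1,17.2,16.0,16.1,16.7
C14,14.9,14.6,14.0,15.1
H27,6.95,7.11,7.24,7.18
H26,6.93,7.10,7.11,7.05
H29,4.21,4.17,4.38,4.23
H23,3.51,3.58,4.05,3.66
H17-19,2.28,2.54,2.64,2.49
"H28,31,33",1.36,1.31,1.38,1.47
"H25,30,32",1.28,1.31,1.31,1.29
H20-22,1.28,1.37,1.40,1.42
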