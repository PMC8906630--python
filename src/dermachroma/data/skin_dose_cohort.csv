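patient_id,upper,lower,inner,outer,mean
1,260.2,251.7,221.8,266.3,250.0
2,271.4,245.5,244.0,233.8,248.7
3,256.0,247.4,202.8,284.0,247.6
4,272.2,229.5,238.1,199.3,234.8
5,262.2,231.0,240.5,213.1,236.7
6,265.2,237.7,212.6,253.7,242.3
7,262.9,232.1,208.4,223.1,231.6
8,228.5,224.7,186.7,219.8,214.9
9,264.6,227.9,209.5,236.6,234.6
10,247.4,217.3,209.7,204.9,219.8
11,249.3,275.0,200.9,217.6,235.7
12,240.4,243.0,203.5,248.9,234.0
13,264.0,274.6,261.8,250.9,262.8
14,246.1,273.7,214.4,202.1,234.1
15,255.6,265.1,199.7,223.9,236.1
16,232.9,244.2,204.4,212.4,223.5
17,223.1,273.1,189.1,203.5,222.2
18,267.9,263.4,198.4,226.4,239.0
19,259.0,252.7,193.7,201.9,226.8
20,234.0,246.0,207.2,213.7,225.2
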