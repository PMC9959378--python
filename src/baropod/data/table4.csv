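rater,Wearing Comfort,Bluetooth Performance,Measurement Accuracy,App Appearance,App Performance,Willingness to Use It
1,4,5,5,5,5,5
2,4,5,4,5,4,5
3,3,5,4,4,5,3
4,5,5,5,5,4,5
5,4,4,5,5,5,5
6,3,5,5,5,5,4
7,4,5,5,5,5,5
8,4,5,5,4,4,5
9,4,5,4,5,4,4
10,4,5,5,5,5,5
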