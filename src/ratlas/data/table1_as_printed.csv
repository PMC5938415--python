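group,level,z_mm
S,1,8.24
S,18,-0.11
PW1,33,-3.80
PW2,35,-3.80
PW3,97,-7.68
PW3,130,-11.64
PW3,1,7.56
PW3,34,-0.12
PW3,65,-3.84
PW1,49,-7.80
PW2,51,-7.80
PW3,98,-7.80
S,59,-11.75
PW3,2,7.08
PW3,35,-0.24
S,32,-3.90
S,45,-7.90
PW3,131,-11.76
PW3,3,6.60
PW1,18,-0.26
PW2,18,-0.26
S,19,-0.26
PW3,66,-3.96
PW3,99,-7.92
PW1,65,-11.80
PW2,67,-11.80
S,2,6.74
PW1,19,-0.30
PW2,19,-0.30
PW3,67,-4.08
PW1,50,-8.00
PW2,52,-8.00
PW3,132,-11.88
PW1,1,6.70
PW2,1,6.70
PW3,36,-0.36
PW1,34,-4.16
PW2,36,-4.16
PW3,100,-8.04
S,60,-11.90
PW1,2,6.20
PW2,2,6.20
PW1,20,-0.40
PW2,20,-0.40
PW3,68,-4.20
S,33,-4.20
PW3,101,-8.16
PW1,66,-11.96
PW2,68,-11.96
PW3,4,6.12
S,20,-0.46
PW1,35,-4.30
PW2,37,-4.30
PW3,102,-8.28
PW3,133,-12.00
S,3,5.88
PW3,37,-0.48
PW3,69,-4.36
PW1,51,-8.30
PW2,53,-8.30
S,46,-8.30
PW3,134,-12.12
PW1,3,5.70
PW2,3,5.70
S,21,-0.51
PW3,70,-4.44
PW3,103,-8.40
S,61,-12.20
PW3,5,5.64
PW3,38,-0.60
S,34,-4.45
PW3,104,-8.52
PW3,135,-12.24
PW1,4,5.20
PW2,4,5.20
S,4,5.20
PW3,39,-0.72
PW1,36,-4.48
PW2,38,-4.48
S,47,-8.60
PW1,67,-12.30
PW2,69,-12.30
PW3,6,5.16
PW1,21,-0.80
PW2,21,-0.80
PW3,71,-4.56
PW3,105,-8.64
PW3,136,-12.36
S,5,4.85
S,22,-0.83
S,35,-4.60
PW1,52,-8.72
PW2,54,-8.72
PW3,137,-12.48
PW1,5,4.70
PW2,5,4.70
PW3,40,-0.84
PW3,72,-4.68
PW3,106,-8.76
S,62,-12.50
PW3,7,4.68
PW1,22,-0.92
PW2,22,-0.92
PW1,37,-4.80
PW2,39,-4.80
PW3,73,-4.80
PW1,53,-8.80
PW2,55,-8.80
PW3,138,-12.60
PW1,6,4.20
PW2,6,4.20
PW3,8,4.20
S,6,4.20
PW3,41,-0.96
PW3,74,-4.92
S,48,-8.85
S,63,-12.68
PW3,9,3.72
PW3,42,-1.08
S,23,-1.08
S,36,-5.00
PW3,107,-8.88
PW1,68,-12.72
PW2,70,-12.72
PW3,139,-12.72
PW1,7,3.70
PW2,7,3.70
PW3,43,-1.20
PW3,75,-5.04
PW3,108,-9.00
PW1,69,-12.80
PW2,71,-12.80
S,7,3.60
PW1,23,-1.30
PW2,23,-1.30
PW3,76,-5.16
PW3,109,-9.12
PW3,140,-12.84
PW3,10,3.24
PW3,44,-1.32
PW1,38,-5.20
PW2,40,-5.20
PW1,54,-9.16
PW2,56,-9.16
S,64,-12.88
PW1,8,3.20
PW2,8,3.20
S,8,3.20
S,24,-1.33
S,37,-5.25
PW3,110,-9.24
PW3,141,-12.96
PW3,11,3.00
PW1,24,-1.40
PW2,24,-1.40
PW3,77,-5.28
S,49,-9.25
PW3,142,-13.08
S,9,2.80
PW3,45,-1.44
PW1,39,-5.30
PW2,41,-5.30
PW1,55,-9.30
PW2,57,-9.30
S,65,-13.15
PW3,12,2.76
S,25,-1.53
PW3,78,-5.40
PW3,111,-9.36
PW3,143,-13.20
PW1,9,2.70
PW2,9,2.70
PW3,46,-1.56
PW3,79,-5.52
PW3,112,-9.48
PW1,70,-13.24
PW2,72,-13.24
PW3,13,2.52
PW2,25,-1.60
PW1,40,-5.60
PW2,42,-5.60
S,50,-9.50
S,66,-13.28
PW3,14,2.28
PW3,47,-1.72
PW3,80,-5.64
PW3,113,-9.60
PW1,71,-13.30
PW2,73,-13.30
PW1,10,2.20
PW2,10,2.20
S,26,-1.78
S,38,-5.65
PW1,56,-9.68
PW2,58,-9.68
PW3,144,-13.32
PW3,15,2.16
PW1,25,-1.80
PW2,26,-1.80
PW3,48,-1.80
PW3,81,-5.76
PW3,114,-9.72
PW3,145,-13.44
S,67,-13.44
S,10,2.15
PW2,27,-1.88
PW1,41,-5.80
PW2,43,-5.80
PW1,57,-9.80
PW2,59,-9.80
S,51,-9.80
PW3,146,-13.56
PW3,16,2.04
PW3,49,-1.92
PW3,82,-5.88
PW3,115,-9.84
S,68,-13.60
PW3,17,1.92
S,27,-2.00
PW3,83,-6.00
PW3,116,-9.96
PW1,72,-13.68
PW2,74,-13.68
PW3,147,-13.68
PW3,18,1.80
PW3,50,-2.04
PW1,42,-6.04
PW2,44,-6.04
PW1,58,-10.04
PW2,60,-10.04
S,69,-13.76
PW1,11,1.70
PW2,11,1.70
S,11,1.70
PW1,26,-2.12
PW2,28,-2.12
S,39,-6.06
PW3,117,-10.08
PW1,73,-13.80
PW2,75,-13.80
PW3,148,-13.80
PW3,19,1.68
PW3,51,-2.16
PW3,84,-6.12
S,52,-10.10
PW3,149,-13.92
PW1,12,1.60
PW2,12,1.60
PW3,52,-2.28
PW3,85,-6.24
PW3,118,-10.20
PW3,150,-14.04
PW3,20,1.56
PW1,27,-2.30
PW2,29,-2.30
PW1,43,-6.30
PW2,45,-6.30
PW1,59,-10.30
PW2,61,-10.30
PW1,74,-14.08
PW2,76,-14.08
S,12,1.45
PW3,53,-2.40
PW3,86,-6.36
PW3,119,-10.32
PW3,151,-14.16
S,70,-14.16
PW3,21,1.44
S,28,-2.45
PW3,87,-6.48
S,53,-10.35
PW3,152,-14.28
PW3,22,1.32
PW3,54,-2.52
S,40,-6.50
PW3,120,-10.44
PW1,75,-14.30
PW2,77,-14.30
PW1,13,1.20
PW2,13,1.20
PW3,23,1.20
S,13,1.20
PW1,28,-2.56
PW2,30,-2.56
PW3,88,-6.60
PW1,60,-10.52
PW2,62,-10.52
S,71,-14.36
PW3,24,1.08
PW3,55,-2.64
S,41,-6.65
PW3,121,-10.56
PW3,153,-14.40
PW1,14,1.00
PW2,14,1.00
PW3,56,-2.76
PW1,44,-6.72
PW2,46,-6.72
PW3,89,-6.72
S,54,-10.60
PW3,154,-14.52
PW3,25,0.96
PW1,29,-2.80
PW2,31,-2.80
PW1,45,-6.80
PW2,47,-6.80
PW3,122,-10.68
PW1,76,-14.60
PW2,78,-14.60
S,14,0.95
S,29,-2.85
PW3,90,-6.84
PW1,61,-10.80
PW2,63,-10.80
PW3,123,-10.80
PW3,155,-14.64
PW3,26,0.84
PW3,57,-2.92
S,42,-6.85
S,55,-10.85
PW3,156,-14.76
PW3,27,0.72
PW3,58,-3.00
PW3,91,-6.96
PW3,124,-10.92
S,72,-14.86
PW1,15,0.70
PW2,15,0.70
PW3,59,-3.12
PW1,46,-7.04
PW2,48,-7.04
PW1,62,-11.00
PW2,64,-11.00
PW3,157,-15.00
PW3,28,0.60
PW1,30,-3.14
PW2,32,-3.14
PW3,92,-7.08
PW3,117,-11.04
PW3,158,-15.24
PW1,16,0.48
PW2,16,0.48
PW3,29,0.48
PW3,60,-3.24
S,43,-7.10
S,52,-11.10
S,73,-15.46
S,15,0.45
S,30,-3.25
PW3,93,-7.20
PW3,118,-11.16
PW3,159,-15.48
PW3,30,0.36
PW1,31,-3.30
PW2,33,-3.30
PW1,47,-7.30
PW2,49,-7.30
PW3,160,-15.72
PW3,31,0.24
PW3,61,-3.36
PW3,94,-7.32
PW1,63,-11.30
PW2,65,-11.30
PW3,119,-11.30
PW3,161,-15.96
PW1,17,0.20
PW2,17,0.20
PW3,62,-3.48
PW3,95,-7.44
S,53,-11.40
PW3,32,0.12
PW1,32,-3.60
PW2,34,-3.60
PW3,63,-3.60
PW3,96,-7.56
PW3,129,-11.52
S,16,0.10
S,31,-3.70
S,44,-7.60
S,58,-11.58
PW3,33,0.00
S,17,0.00
PW3,64,-3.72
PW1,48,-7.64
PW2,50,-7.64
PW1,64,-11.60
PW2,66,-11.60
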